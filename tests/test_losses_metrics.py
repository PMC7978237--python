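"""Metric formulas against exact rational arithmetic, soft-MCC loss
contracts, and ROC properties."""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from cineseg.losses_metrics import (
    ClassWeights,
    ConfusionCounts,
    MetricSet,
    compute_metrics,
    confusion_from_masks,
    harden,
    mcc_loss,
    per_class_metrics,
    roc_curve,
    soft_mcc,
)
from cineseg.cine_io import MaskStack
from cineseg.model_zoo import SegOutput
from cineseg.nn import Tensor


def rational_metrics(tp: int, tn: int, fp: int, fn: int):
    """Independent exact-arithmetic oracle for the five metrics."""
    def ratio(num, den, fallback):
        return fallback if den == 0 else Fraction(num, den)

    perfect = 1 if (fp == 0 and fn == 0) else 0
    iou = ratio(tp, tp + fn + fp, perfect)
    recall = ratio(tp, tp + fn, perfect)
    precision = ratio(tp, tp + fp, perfect)
    f2 = ratio(5 * tp, 5 * tp + 4 * fn + fp, perfect)
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = perfect if den == 0 else (tp * tn - fp * fn) / math.sqrt(den)
    return dict(iou=float(iou), recall=float(recall), precision=float(precision),
                f2=float(f2), mcc=float(mcc))


def test_metrics_match_rational_oracle_on_random_counts():
    rng = np.random.default_rng(0)
    for _ in range(1000):
        tp, tn, fp, fn = (int(v) for v in rng.integers(0, 500, size=4))
        if tp + tn + fp + fn == 0:
            tp = 1
        got = compute_metrics(ConfusionCounts(tp, tn, fp, fn)).as_dict()
        want = rational_metrics(tp, tn, fp, fn)
        for key in want:
            assert got[key] == pytest.approx(want[key], abs=1e-12), (key, tp, tn, fp, fn)


@pytest.mark.parametrize(
    "counts,expected",
    [
        # perfect prediction
        ((1, 1, 0, 0), dict(iou=1, mcc=1, recall=1, precision=1, f2=1)),
        # hand-evaluated mixed case; MCC = (10*80-25)/sqrt(15*15*85*85)
        ((10, 80, 5, 5),
         dict(iou=0.5, recall=2 / 3, precision=2 / 3, f2=50 / 75,
              mcc=(10 * 80 - 25) / math.sqrt(15 * 15 * 85 * 85))),
        # class absent in both prediction and truth: vacuously perfect
        ((0, 100, 0, 0), dict(iou=1, mcc=1, recall=1, precision=1, f2=1)),
        # absent in truth but predicted: zero by convention
        ((0, 90, 10, 0), dict(iou=0, recall=0, precision=0, f2=0, mcc=0)),
    ],
)
def test_metric_examples(counts, expected):
    got = compute_metrics(ConfusionCounts(*counts)).as_dict()
    for key, val in expected.items():
        assert got[key] == pytest.approx(val, abs=1e-12)


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        ConfusionCounts(-1, 0, 0, 1)


def test_f2_lies_between_precision_and_recall():
    rng = np.random.default_rng(3)
    for _ in range(200):
        tp, tn, fp, fn = (int(v) + 1 for v in rng.integers(0, 50, size=4))
        m = compute_metrics(ConfusionCounts(tp, tn, fp, fn))
        lo, hi = sorted((m.precision, m.recall))
        assert lo - 1e-12 <= m.f2 <= hi + 1e-12


def test_confusion_counts_match_per_pixel_loop(rng):
    pred = rng.integers(0, 2, size=(3, 16, 16))
    truth = rng.integers(0, 2, size=(3, 16, 16))
    got = confusion_from_masks(pred, truth)
    tp = tn = fp = fn = 0
    for p, t in zip(pred.ravel(), truth.ravel()):
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    assert (got.tp, got.tn, got.fp, got.fn) == (tp, tn, fp, fn)
    assert got.total == pred.size
    same = confusion_from_masks(truth, truth)
    assert same.fp == 0 and same.fn == 0
    compl = confusion_from_masks(1 - truth, truth)
    assert compl.tp == 0 and compl.tn == 0


def test_confusion_shape_mismatch_named():
    with pytest.raises(ValueError, match="shape mismatch"):
        confusion_from_masks(np.zeros((2, 4, 4)), np.zeros((2, 5, 4)))


# ---------------------------------------------------------------------------
# soft-MCC loss


def _random_truth(rng, t=2, h=12, w=12):
    lesion = np.zeros((t, h, w), np.uint8)
    lesion[:, 2:5, 2:5] = 1
    lesion[:, 7:10, 6:10] = 2
    thyroid = np.zeros((t, h, w), np.uint8)
    thyroid[:, 1:11, 1:11] = 1
    return MaskStack(thyroid, lesion)


def _saturated_seg(truth):
    thy = truth.thyroid.astype(np.float32)
    lesion = np.zeros((*truth.lesion.shape, 3), np.float32)
    for c in range(3):
        lesion[..., c] = truth.lesion == c
    return SegOutput(thy, np.moveaxis(lesion, -1, 1))


def test_loss_near_zero_for_perfect_saturated_prediction(rng):
    truth = _random_truth(rng)
    loss = float(mcc_loss(_saturated_seg(truth), truth).data)
    assert 0 <= loss < 1e-3


def test_empty_truth_confident_fp_costs_more_and_has_gradient():
    t, h, w = 1, 8, 8
    truth = MaskStack(np.zeros((t, h, w), np.uint8), np.zeros((t, h, w), np.uint8))
    wts = ClassWeights()

    def loss_for(p_const):
        thy = Tensor(np.full((t, h, w), p_const, np.float32), requires_grad=True)
        les = np.zeros((t, 3, h, w), np.float32)
        les[:, 0] = 1 - p_const
        les[:, 2] = p_const
        seg = SegOutput(thy, Tensor(les))
        out = mcc_loss(seg, truth, wts)
        out.backward()
        return float(out.data), float(np.abs(thy.grad).max())

    loss_fp, grad_fp = loss_for(0.95)
    loss_ok, _ = loss_for(0.001)
    assert loss_fp > loss_ok
    assert np.isfinite(grad_fp) and grad_fp > 0


def test_loss_decreases_along_truth_interpolation_path(rng):
    truth = _random_truth(rng)
    losses = []
    for t_ in (0.0, 0.25, 0.5, 0.75, 1.0):
        thy = t_ * truth.thyroid + (1 - t_) * (1 - truth.thyroid)
        les = np.zeros((*truth.lesion.shape, 3), np.float32)
        for c in range(3):
            y = (truth.lesion == c).astype(np.float32)
            les[..., c] = t_ * y + (1 - t_) * (1 - y)
        les /= les.sum(axis=-1, keepdims=True)
        seg = SegOutput(thy.astype(np.float32), np.moveaxis(les, -1, 1))
        losses.append(float(mcc_loss(seg, truth).data))
    assert all(a > b for a, b in zip(losses, losses[1:])), losses


def test_hard_prediction_loss_equals_one_minus_weighted_hard_mcc(rng):
    truth = _random_truth(rng)
    pred_thy = rng.integers(0, 2, truth.thyroid.shape).astype(np.float32)
    wts = ClassWeights(background=0.2, thyroid=0.3, cyst=1.0, nodule=1.0)
    wmap = np.full(truth.lesion.shape, wts.background, np.float32)
    wmap[truth.thyroid.astype(bool)] = wts.thyroid
    wmap[truth.lesion == 1] = wts.cyst
    wmap[truth.lesion == 2] = wts.nodule
    y = truth.thyroid.astype(bool)
    p = pred_thy.astype(bool)
    tp = wmap[p & y].sum()
    fp = wmap[p & ~y].sum()
    fn = wmap[~p & y].sum()
    tn = wmap[~p & ~y].sum()
    hard = (tp * tn - fp * fn) / math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    soft = float(soft_mcc(Tensor(pred_thy), truth.thyroid, wmap).data)
    assert soft == pytest.approx(hard, abs=1e-3)


def test_loss_invariant_under_pixel_permutation_and_flip(rng):
    truth = _random_truth(rng)
    thy = rng.random(truth.thyroid.shape).astype(np.float32)
    les = rng.random((truth.lesion.shape[0], 3, *truth.lesion.shape[1:])).astype(np.float32)
    les /= les.sum(axis=1, keepdims=True)
    base = float(mcc_loss(SegOutput(thy, les), truth).data)
    flipped = float(
        mcc_loss(
            SegOutput(thy[:, :, ::-1].copy(), les[:, :, :, ::-1].copy()),
            MaskStack(truth.thyroid[:, :, ::-1].copy(), truth.lesion[:, :, ::-1].copy()),
        ).data
    )
    assert flipped == pytest.approx(base, rel=1e-6)
    perm = rng.permutation(truth.thyroid.size)

    def permute(a):
        return a.reshape(-1)[perm].reshape(a.shape)

    permuted = float(
        mcc_loss(
            SegOutput(
                permute(thy),
                np.stack([permute(les[:, c]) for c in range(3)], axis=1),
            ),
            MaskStack(permute(truth.thyroid), permute(truth.lesion)),
        ).data
    )
    assert permuted == pytest.approx(base, rel=1e-6)


def test_loss_rejects_nonpositive_eps(rng):
    truth = _random_truth(rng)
    with pytest.raises(ValueError):
        mcc_loss(_saturated_seg(truth), truth, eps=0.0)


def test_class_weights_validation():
    with pytest.raises(ValueError):
        ClassWeights(background=-1.0)
    with pytest.raises(ValueError):
        ClassWeights(0.0, 0.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# ROC


def test_roc_perfect_separation():
    labels = np.array([0, 0, 1, 1, 0, 1])
    fpr, tpr, area = roc_curve(labels.astype(float), labels)
    assert area == pytest.approx(1.0)
    assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)


def test_roc_random_scores_near_half_and_matches_mannwhitney(rng):
    n = 10_000
    scores = rng.random(n)
    labels = rng.integers(0, 2, n)
    _, _, area = roc_curve(scores, labels)
    assert area == pytest.approx(0.5, abs=0.02)
    u = mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
    auc_mw = u / ((labels == 1).sum() * (labels == 0).sum())
    assert area == pytest.approx(auc_mw, abs=1e-9)


def test_roc_negated_scores_complement(rng):
    scores = rng.random(500)
    labels = (rng.random(500) < 0.3).astype(int)
    _, _, a1 = roc_curve(scores, labels)
    _, _, a2 = roc_curve(-scores, labels)
    assert a1 + a2 == pytest.approx(1.0, abs=1e-9)


def test_roc_single_class_error():
    with pytest.raises(ValueError):
        roc_curve(np.array([0.1, 0.9]), np.array([1, 1]))


def test_harden_and_per_class_metrics_roundtrip(rng):
    truth = _random_truth(rng)
    seg = _saturated_seg(truth)
    thy, les = harden(seg)
    metrics = per_class_metrics(thy, les, truth)
    for cls in ("thyroid", "cyst", "nodule"):
        assert metrics[cls].iou == pytest.approx(1.0)
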