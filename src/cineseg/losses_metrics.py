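"""Segmentation metrics and the class-balanced soft-MCC training loss.

Five confusion-matrix metrics are reported throughout the package:

.. math::

    IoU  &= TP / (TP + FN + FP) \\\\
    MCC  &= (TP\\,TN - FP\\,FN) / \\sqrt{(TP+FP)(TP+FN)(TN+FP)(TN+FN)} \\\\
    Recall &= TP / (TP + FN) \\\\
    Precision &= TP / (TP + FP) \\\\
    F2 &= 5TP / (5TP + 4FN + FP)

Zero-denominator convention (applied uniformly to all five metrics): a
metric whose denominator vanishes is 1 when the prediction is perfect for
that class (FP = FN = 0, e.g. the class is absent in both prediction and
truth) and 0 otherwise (e.g. the class is absent in truth but predicted).

The training loss is one minus a mean of per-class *soft* MCC values
computed from probability maps.  Every pixel contributes to the four soft
counts with the weight of its ground-truth class, which is how background
and thyroid (the overwhelming majority classes) are down-weighted relative
to cysts and nodules.  A small ``eps`` is added to each soft count so the
loss stays informative when a class has no positive pixels in the target:
a confident false positive then still raises the loss and receives a finite
gradient, unlike overlap losses (Dice and relatives) which are identically
zero there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.metrics import roc_curve as _sk_roc_curve

from .nn import Tensor, as_tensor

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "ClassWeights",
    "compute_metrics",
    "confusion_from_masks",
    "mcc_loss",
    "soft_mcc",
    "roc_curve",
    "per_class_metrics",
    "LESION_CODES",
]

LESION_CODES = {"background": 0, "cyst": 1, "nodule": 2}


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN counts; soft (real-valued) counts are permitted."""

    tp: float
    tn: float
    fp: float
    fn: float

    def __post_init__(self):
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative confusion count {name}={getattr(self, name)}")

    @property
    def total(self) -> float:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    iou: float
    mcc: float
    recall: float
    precision: float
    f2: float

    def as_dict(self) -> dict[str, float]:
        return {
            "iou": self.iou,
            "mcc": self.mcc,
            "recall": self.recall,
            "precision": self.precision,
            "f2": self.f2,
        }


def _safe_ratio(num: float, den: float, counts: ConfusionCounts) -> float:
    if den == 0:
        return 1.0 if (counts.fp == 0 and counts.fn == 0) else 0.0
    return num / den


def compute_metrics(counts: ConfusionCounts) -> MetricSet:
    """Evaluate IoU, MCC, recall, precision and F2 from confusion counts."""
    if counts.total <= 0:
        raise ValueError("all confusion counts are zero")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    iou = _safe_ratio(tp, tp + fn + fp, counts)
    recall = _safe_ratio(tp, tp + fn, counts)
    precision = _safe_ratio(tp, tp + fp, counts)
    f2 = _safe_ratio(5 * tp, 5 * tp + 4 * fn + fp, counts)
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if den == 0:
        mcc = 1.0 if (fp == 0 and fn == 0) else 0.0
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(den)
    return MetricSet(iou=iou, mcc=mcc, recall=recall, precision=precision, f2=f2)


def confusion_from_masks(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixel-wise confusion counts of two equally-shaped binary masks."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    p = pred.astype(bool)
    t = truth.astype(bool)
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


@dataclass
class ClassWeights:
    """Per-class loss weights for {background, thyroid, cyst, nodule}."""

    background: float = 0.1
    thyroid: float = 0.1
    cyst: float = 1.0
    nodule: float = 1.0

    def __post_init__(self):
        vals = (self.background, self.thyroid, self.cyst, self.nodule)
        if any(v < 0 for v in vals):
            raise ValueError("class weights must be non-negative")
        if all(v == 0 for v in vals):
            raise ValueError("at least one class weight must be positive")

    @classmethod
    def inverse_frequency(cls, thyroid_masks, lesion_masks,
                          majority_downweight: float = 0.1) -> "ClassWeights":
        """Inverse pixel-frequency weights from training masks.

        Background and thyroid weights are additionally multiplied by
        ``majority_downweight`` (majority-class down-weighting).  Weights are
        normalised so the nodule weight is 1.
        """
        thy = np.concatenate([np.asarray(m).ravel() for m in thyroid_masks])
        les = np.concatenate([np.asarray(m).ravel() for m in lesion_masks])
        total = les.size
        n_cyst = max(int(np.count_nonzero(les == 1)), 1)
        n_nod = max(int(np.count_nonzero(les == 2)), 1)
        n_thy = max(int(np.count_nonzero(thy)), 1)
        n_bg = max(total - n_cyst - n_nod - n_thy, 1)
        raw = {
            "background": total / n_bg * majority_downweight,
            "thyroid": total / n_thy * majority_downweight,
            "cyst": total / n_cyst,
            "nodule": total / n_nod,
        }
        scale = 1.0 / raw["nodule"]
        return cls(**{k: v * scale for k, v in raw.items()})


def _pixel_weight_map(thyroid_true: np.ndarray, lesion_true: np.ndarray,
                      weights: ClassWeights) -> np.ndarray:
    """Weight of each pixel's ground-truth class (lesions take precedence)."""
    w = np.full(lesion_true.shape, weights.background, dtype=np.float32)
    w[np.asarray(thyroid_true, bool)] = weights.thyroid
    w[lesion_true == LESION_CODES["cyst"]] = weights.cyst
    w[lesion_true == LESION_CODES["nodule"]] = weights.nodule
    return w


def soft_mcc(prob: Tensor, target: np.ndarray, weight_map: np.ndarray,
             eps: float = 1e-6) -> Tensor:
    """Differentiable weighted MCC of a probability map against a binary target.

    ``eps`` is added to each of the four weighted soft counts (and inside the
    square root), which keeps the statistic finite and informative when the
    target contains no positives.
    """
    prob = as_tensor(prob, np.float32)
    y = np.asarray(target, np.float32)
    w = Tensor(np.asarray(weight_map, np.float32))
    yt = Tensor(y)
    wp = w * prob
    wn = w * (1.0 - prob)
    tp = (wp * yt).sum() + eps
    fp = (wp * (1.0 - yt)).sum() + eps
    fn = (wn * yt).sum() + eps
    tn = (wn * (1.0 - yt)).sum() + eps
    num = tp * tn - fp * fn
    den = ((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn) + eps) ** 0.5
    return num / den


def mcc_loss(seg, truth, weights: ClassWeights | None = None,
             eps: float = 1e-6) -> Tensor:
    """Class-balanced soft-MCC loss for the dual-output model.

    Parameters
    ----------
    seg
        An object with ``thyroid_prob`` (sigmoid map, [T,H,W] or [T,1,H,W])
        and optionally ``lesion_prob`` (softmax map, [T,3,H,W]); either may
        be a :class:`~cineseg.nn.Tensor` (training) or a numpy array.
    truth
        An object with binary ``thyroid`` and integer ``lesion`` layers of
        shape [T,H,W] (codes 0=background, 1=cyst, 2=nodule).
    weights
        Per-class weights; defaults down-weight background and thyroid.
    eps
        Smoothing added to each soft count; must be positive.

    Returns
    -------
    Tensor
        ``1 - mean_head(mean_class(soft MCC))``; a non-negative scalar in
        [0, 2] with gradients defined everywhere.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    weights = weights or ClassWeights()
    thyroid_true = np.asarray(truth.thyroid)
    lesion_true = np.asarray(truth.lesion)
    wmap = _pixel_weight_map(thyroid_true, lesion_true, weights)

    thy_prob = as_tensor(seg.thyroid_prob, np.float32)
    if thy_prob.ndim == 4:  # (T,1,H,W) -> (T,H,W)
        thy_prob = thy_prob.reshape(thy_prob.shape[0], *thy_prob.shape[2:])
    head_means = [soft_mcc(thy_prob, thyroid_true, wmap, eps)]

    lesion_prob = getattr(seg, "lesion_prob", None)
    if lesion_prob is not None:
        lesion_prob = as_tensor(lesion_prob, np.float32)
        class_mccs = []
        for name in ("cyst", "nodule"):
            code = LESION_CODES[name]
            prob_c = lesion_prob[:, code]
            class_mccs.append(soft_mcc(prob_c, lesion_true == code, wmap, eps))
        mean_lesion = class_mccs[0]
        for m in class_mccs[1:]:
            mean_lesion = mean_lesion + m
        head_means.append(mean_lesion * (1.0 / len(class_mccs)))

    total = head_means[0]
    for h in head_means[1:]:
        total = total + h
    return 1.0 - total * (1.0 / len(head_means))


def roc_curve(scores: np.ndarray, labels: np.ndarray):
    """ROC points and area for per-pixel scores against binary labels.

    Returns ``(fpr, tpr, area)``; the area equals the probability that a
    random positive outscores a random negative (ties counted half).
    """
    scores = np.asarray(scores).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("roc_curve requires both positive and negative labels")
    fpr, tpr, _ = _sk_roc_curve(labels, scores)
    area = float(roc_auc_score(labels, scores))
    return fpr, tpr, area


def per_class_metrics(pred_thyroid: np.ndarray, pred_lesion: np.ndarray,
                      truth) -> Mapping[str, MetricSet]:
    """Hard per-class metrics (thyroid, cyst, nodule) of a prediction."""
    out = {}
    out["thyroid"] = compute_metrics(
        confusion_from_masks(pred_thyroid, np.asarray(truth.thyroid))
    )
    lesion_true = np.asarray(truth.lesion)
    pred_lesion = np.asarray(pred_lesion)
    for name in ("cyst", "nodule"):
        code = LESION_CODES[name]
        out[name] = compute_metrics(
            confusion_from_masks(pred_lesion == code, lesion_true == code)
        )
    return out


def harden(seg) -> tuple[np.ndarray, np.ndarray]:
    """Threshold/argmax a probabilistic segmentation to hard label maps."""
    thy = np.asarray(
        seg.thyroid_prob.data if isinstance(seg.thyroid_prob, Tensor) else seg.thyroid_prob
    )
    if thy.ndim == 4:
        thy = thy[:, 0]
    thy_mask = thy >= 0.5
    lesion_prob = getattr(seg, "lesion_prob", None)
    if lesion_prob is None:
        lesion = np.zeros(thy_mask.shape, np.uint8)
    else:
        lp = np.asarray(lesion_prob.data if isinstance(lesion_prob, Tensor) else lesion_prob)
        lesion = lp.argmax(axis=1).astype(np.uint8)
    return thy_mask, lesion
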