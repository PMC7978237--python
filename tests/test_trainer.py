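"""Augmentation semantics, stage plans, freezing schedule and smoke training."""

import numpy as np
import pytest

from cineseg.cine_io import PAD_VALUE
from cineseg.model_zoo import ModelConfig, build_static_model, tiny_config
from cineseg.trainer import (
    AugOp,
    AugmentationScheme,
    StagePlan,
    TrainState,
    augment,
    cohort_from_manifest,
    default_schemes,
    default_stage_plans,
    evaluate_model,
    run_full_protocol,
    run_stage,
)


@pytest.fixture()
def stack(rng):
    frames = rng.random((4, 32, 32)).astype(np.float32)
    frames[:, :, 28:] = PAD_VALUE  # sentinel stripe
    thyroid = np.zeros((4, 32, 32), np.uint8)
    thyroid[:, 8:24, 4:20] = 1
    lesion = np.zeros_like(thyroid)
    lesion[:, 12:16, 8:12] = 2
    return frames, thyroid, lesion


def _scheme(*ops):
    return AugmentationScheme(tuple(ops))


def test_hflip_is_an_involution(stack, rng):
    frames, thy, les = stack
    scheme = _scheme(AugOp("hflip", 1.0))
    f1, t1, l1 = augment(frames, thy, les, scheme, rng)
    f2, t2, l2 = augment(f1, t1, l1, scheme, rng)
    assert np.array_equal(f2, frames)
    assert np.array_equal(t2, thy) and np.array_equal(l2, les)


def test_null_scheme_is_identity(stack, rng):
    frames, thy, les = stack
    scheme = _scheme(*(AugOp(op, 0.0, 5) for op in ("hflip", "rotate", "translate",
                                                    "color_shift")))
    f, t, l = augment(frames, thy, les, scheme, rng)
    assert np.array_equal(f, frames)
    assert np.array_equal(t, thy) and np.array_equal(l, les)


@pytest.mark.parametrize("scale", [15.0, 5.0])
def test_rotation_magnitude_honors_bound(stack, scale):
    frames, thy, les = stack
    # displacement of the mask centroid under rotation by ≤ θ around the
    # canvas center is bounded by 2·r·sin(θ/2)
    ys, xs = np.nonzero(thy[0])
    cy, cx = ys.mean(), xs.mean()
    r = np.hypot(cy - 15.5, cx - 15.5)
    bound = 2 * r * np.sin(np.radians(scale) / 2) + 1.5  # +1.5 px rasterisation
    rng = np.random.default_rng(0)
    scheme = _scheme(AugOp("rotate", 1.0, scale))
    worst = 0.0
    for _ in range(100):
        _, t, _ = augment(frames, thy, les, scheme, rng)
        ys2, xs2 = np.nonzero(t[0])
        worst = max(worst, float(np.hypot(ys2.mean() - cy, xs2.mean() - cx)))
    assert worst <= bound
    assert worst > 0.2  # rotations actually happened


def test_color_shift_touches_tissue_only(stack):
    frames, thy, les = stack
    rng = np.random.default_rng(3)
    scheme = _scheme(AugOp("color_shift", 1.0, 0.05))
    f, _, _ = augment(frames, thy, les, scheme, rng)
    assert np.array_equal(f == PAD_VALUE, frames == PAD_VALUE)
    tissue = frames != PAD_VALUE
    assert not np.array_equal(f[tissue], frames[tissue])
    assert f[tissue].min() >= 0 and f[tissue].max() <= 1
    delta = f[tissue] - frames[tissue]
    interior = np.abs(delta) > 0
    assert np.abs(delta).max() <= 0.05 + 1e-6


def test_translate_and_crop_preserve_label_vocabulary(stack):
    frames, thy, les = stack
    rng = np.random.default_rng(5)
    scheme = _scheme(AugOp("translate", 1.0, 0.10), AugOp("crop", 1.0, 24))
    f, t, l = augment(frames, thy, les, scheme, rng)
    assert set(np.unique(l)) <= {0, 1, 2}
    assert set(np.unique(t)) <= {0, 1}
    assert f.shape == frames.shape
    vals = f[f != PAD_VALUE]
    assert vals.min() >= 0 and vals.max() <= 1


def test_reverse_sequence_requires_sequence_mode(stack, rng):
    frames, thy, les = stack
    scheme = _scheme(AugOp("reverse_sequence", 1.0))
    with pytest.raises(ValueError, match="sequence"):
        augment(frames, thy, les, scheme, rng, sequence_mode=False)
    f, t, l = augment(frames, thy, les, scheme, rng, sequence_mode=True)
    assert np.array_equal(f, frames[::-1])
    assert np.array_equal(l, les[::-1])


def test_default_schemes_match_the_training_table():
    schemes = default_schemes()
    by_stage = {
        s: {op.op: (op.frequency, op.scale) for op in schemes[s].ops} for s in schemes
    }
    assert by_stage[1] == {
        "hflip": (0.5, 0.0), "rotate": (0.25, 15), "translate": (0.25, 0.10),
        "color_shift": (0.10, 0.05), "crop": (1.0, 300),
    }
    assert by_stage[2] == {
        "hflip": (0.5, 0.0), "translate": (0.25, 0.10),
        "color_shift": (0.10, 0.05), "crop": (1.0, 256),
    }
    assert by_stage[3]["rotate"] == (0.50, 5)
    assert by_stage[4] == {"hflip": (0.5, 0.0), "reverse_sequence": (0.5, 0.0)}
    for s in schemes:
        assert all(0 <= op.frequency <= 1 for op in schemes[s].ops)


def test_stage2_oversampling_default_is_two_thirds():
    plans = default_stage_plans()
    assert plans[2].sampler_policy == "forced_nodule"
    assert plans[2].forced_nodule_ratio == pytest.approx(2 / 3)


# ---------------------------------------------------------------------------
# stage orchestration (smoke scale)


def _smoke_config():
    return tiny_config(canvas=32, block_counts=(1, 1, 1, 1), recurrent_filters=4)


def _smoke_plans(seed=0):
    plans = default_stage_plans(seed)
    plans[1].epochs, plans[1].steps_per_epoch, plans[1].batch_size = 5, 6, 4
    plans[2].epochs, plans[2].steps_per_epoch, plans[2].batch_size = 2, 5, 4
    plans[3].epochs, plans[3].steps_per_epoch = 1, 3
    plans[4].epochs, plans[4].steps_per_epoch = 2, 4
    return plans


@pytest.fixture(scope="module")
def smoke_cohort():
    from cineseg.cine_io import split_by_patient
    from cineseg.synthetic_cine import generate_cohort

    clips, man = generate_cohort(6, seed=21, canvas=(32, 32), n_frames=8,
                                 varied_aspect=False)
    man = split_by_patient(man, (0.7, 0.15, 0.15), seed=21)
    return cohort_from_manifest(clips, man)


def test_stage1_training_loss_decreases(smoke_cohort):
    plans = _smoke_plans()
    state, hist = run_stage(plans[1], TrainState(config=_smoke_config()), smoke_cohort)
    losses = [h["loss"] for h in hist]
    assert losses[-1] < losses[0]
    assert state.static_model is not None and state.static_model.stage == 1


def test_stage1_reproducible_for_fixed_seed(smoke_cohort):
    results = []
    for _ in range(2):
        plans = _smoke_plans(seed=5)
        _, hist = run_stage(plans[1], TrainState(config=_smoke_config()), smoke_cohort)
        results.append(hist[-1]["loss"])
    assert results[0] == pytest.approx(results[1], abs=1e-6)


def test_stage_order_is_enforced(smoke_cohort):
    plans = _smoke_plans()
    with pytest.raises(ValueError, match="stage 3"):
        run_stage(plans[3], TrainState(config=_smoke_config()), smoke_cohort)


def test_stage3_freezes_exactly_through_aspp(smoke_cohort):
    cfg = _smoke_config()
    model = build_static_model(cfg, 2, seed=0)
    model.freeze_through_aspp()
    frozen = {n for n, p in model.named_parameters() if not p.requires_grad}
    trainable = {n for n, p in model.named_parameters() if p.requires_grad}
    assert frozen and trainable
    for name in frozen:
        assert name.startswith(("backbone.stem", "backbone.stages", "backbone.aspp"))
    for name in trainable:
        assert name.startswith(("backbone.fusions", "thyroid_head", "lesion_head"))


def test_frozen_backbone_unchanged_by_stage4(smoke_cohort):
    plans = _smoke_plans()
    state = TrainState(config=_smoke_config())
    for stage in (1, 2, 3):
        state, _ = run_stage(plans[stage], state, smoke_cohort)
    before = {
        n: p.data.copy() for n, p in state.static_model.backbone.named_parameters()
    }
    state, _ = run_stage(plans[4], state, smoke_cohort)
    after = dict(state.recurrent_model.backbone.named_parameters())
    for name, arr in before.items():
        assert np.array_equal(arr, after[name].data), name


def test_full_protocol_chains_and_truncates(smoke_cohort):
    cfg = _smoke_config()
    state, hists = run_full_protocol(cfg, smoke_cohort, seed=0, plans=_smoke_plans(),
                                     stages=(1,))
    assert state.recurrent_model is None
    assert state.static_model.stage == 1
    assert set(hists) == {1}


def test_pretrain_fallback_warns(smoke_cohort):
    cohort = dict(smoke_cohort)
    cohort["pretrain"] = []
    plans = _smoke_plans()
    with pytest.warns(UserWarning, match="falling back"):
        run_stage(plans[1], TrainState(config=_smoke_config()), cohort)


def test_evaluate_model_reports_per_class_means(smoke_cohort):
    plans = _smoke_plans()
    state, _ = run_stage(plans[1], TrainState(config=_smoke_config()), smoke_cohort)
    report = evaluate_model(state.static_model, smoke_cohort["validation"],
                            classes=("thyroid",))
    assert set(report) == {"thyroid"}
    assert set(report["thyroid"]) == {"iou", "mcc", "recall", "precision", "f2"}
    assert 0 <= report["thyroid"]["iou"] <= 1
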