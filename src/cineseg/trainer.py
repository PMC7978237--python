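"""Four-stage training protocol with per-stage augmentation schemes.

Stage 1 pre-trains a single-output (thyroid-only) static model on the
pre-training superset.  Stage 2 introduces the lesion softmax head and
retrains on the training set with nodule oversampling (two forced-nodule
batches for every three random batches at the default ratio 2/3).  Stage 3
freezes the encoder through the ASPP module and trains the remaining
output layers on full frame sequences.  Stage 4 adapts the frozen encoder
into the windowed recurrent model and trains the recurrent module and new
heads on full sequences.

Augmentation follows a fixed per-stage table: horizontal flips, bounded
rotations and translations, global intensity ("color") shifts applied to
tissue pixels only, random crops resized back to the canvas, and — for the
sequence stage — temporal reversal.  Geometric operations are applied
identically to frames and masks (nearest-neighbour for masks) and never
touch the −1 padding sentinel's semantics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage as ndi

from .cine_io import (
    CineClip,
    DatasetManifest,
    MaskStack,
    PAD_VALUE,
    resize_with_padding,
    sample_training_batches,
)
from .losses_metrics import ClassWeights, mcc_loss, harden, per_class_metrics
from .model_zoo import (
    ModelConfig,
    RecurrentModel,
    StaticModel,
    build_recurrent_model,
    build_static_model,
    segment_cineclip,
)
from .nn import Adam, Tensor

__all__ = [
    "AugOp",
    "AugmentationScheme",
    "StagePlan",
    "TrainState",
    "augment",
    "default_schemes",
    "default_stage_plans",
    "run_stage",
    "run_full_protocol",
    "evaluate_model",
    "cohort_from_manifest",
]

AUG_OPS = ("hflip", "rotate", "translate", "color_shift", "crop", "reverse_sequence")


@dataclass(frozen=True)
class AugOp:
    op: str
    frequency: float
    scale: float = 0.0  # degrees (rotate), fraction (translate/color), pixels (crop)

    def __post_init__(self):
        if self.op not in AUG_OPS:
            raise ValueError(f"unknown augmentation op {self.op!r}")
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError("frequency must be in [0, 1]")


@dataclass(frozen=True)
class AugmentationScheme:
    ops: tuple[AugOp, ...]

    def has(self, name: str) -> bool:
        return any(o.op == name for o in self.ops)


def default_schemes() -> dict[int, AugmentationScheme]:
    """The per-stage augmentation table used during training."""
    return {
        1: AugmentationScheme((
            AugOp("hflip", 0.50),
            AugOp("rotate", 0.25, 15),
            AugOp("translate", 0.25, 0.10),
            AugOp("color_shift", 0.10, 0.05),
            AugOp("crop", 1.00, 300),
        )),
        2: AugmentationScheme((
            AugOp("hflip", 0.50),
            AugOp("translate", 0.25, 0.10),
            AugOp("color_shift", 0.10, 0.05),
            AugOp("crop", 1.00, 256),
        )),
        3: AugmentationScheme((
            AugOp("hflip", 0.50),
            AugOp("rotate", 0.50, 5),
            AugOp("translate", 0.25, 0.10),
            AugOp("color_shift", 0.10, 0.05),
            AugOp("crop", 1.00, 256),
        )),
        4: AugmentationScheme((
            AugOp("hflip", 0.50),
            AugOp("reverse_sequence", 0.50),
        )),
    }


def augment(frames: np.ndarray, thyroid: np.ndarray, lesion: np.ndarray,
            scheme: AugmentationScheme, rng: np.random.Generator, *,
            sequence_mode: bool = False):
    """Apply a scheme to a frame stack and its masks (identically).

    Each op fires independently with its frequency; one draw per call, so a
    sequence is transformed coherently.  Returns new arrays.
    """
    frames = np.asarray(frames, np.float32).copy()
    thyroid = np.asarray(thyroid).copy()
    lesion = np.asarray(lesion).copy()
    canvas = frames.shape[1:]
    for op in scheme.ops:
        if op.op == "reverse_sequence" and not sequence_mode:
            raise ValueError("reverse_sequence is only valid in sequence mode")
        if rng.random() >= op.frequency:
            continue
        if op.op == "hflip":
            frames = frames[:, :, ::-1].copy()
            thyroid = thyroid[:, :, ::-1].copy()
            lesion = lesion[:, :, ::-1].copy()
        elif op.op == "rotate":
            angle = float(rng.uniform(-op.scale, op.scale))
            frames = np.stack([
                ndi.rotate(f, angle, reshape=False, order=1, cval=PAD_VALUE,
                           prefilter=False)
                for f in frames
            ])
            frames = np.clip(frames, PAD_VALUE, 1.0)
            thyroid = np.stack([
                ndi.rotate(m, angle, reshape=False, order=0, cval=0) for m in thyroid
            ])
            lesion = np.stack([
                ndi.rotate(m, angle, reshape=False, order=0, cval=0) for m in lesion
            ])
        elif op.op == "translate":
            dy = float(rng.uniform(-op.scale, op.scale)) * canvas[0]
            dx = float(rng.uniform(-op.scale, op.scale)) * canvas[1]
            frames = np.stack([
                ndi.shift(f, (dy, dx), order=1, cval=PAD_VALUE, prefilter=False)
                for f in frames
            ])
            frames = np.clip(frames, PAD_VALUE, 1.0)
            thyroid = np.stack([ndi.shift(m, (dy, dx), order=0, cval=0) for m in thyroid])
            lesion = np.stack([ndi.shift(m, (dy, dx), order=0, cval=0) for m in lesion])
        elif op.op == "color_shift":
            delta = float(rng.uniform(-op.scale, op.scale))
            tissue = frames != PAD_VALUE
            frames[tissue] = np.clip(frames[tissue] + delta, 0.0, 1.0)
        elif op.op == "crop":
            size = int(min(op.scale, *canvas))
            if size < min(canvas):
                top = int(rng.integers(0, canvas[0] - size + 1))
                left = int(rng.integers(0, canvas[1] - size + 1))
                target = max(canvas)
                fr = frames[:, top : top + size, left : left + size]
                frames = np.stack(
                    [resize_with_padding(f, target)[0] for f in fr]
                )
                thyroid = np.stack([
                    resize_with_padding(m[top : top + size, left : left + size],
                                        target, is_mask=True)[0]
                    for m in thyroid
                ])
                lesion = np.stack([
                    resize_with_padding(m[top : top + size, left : left + size],
                                        target, is_mask=True)[0]
                    for m in lesion
                ])
        elif op.op == "reverse_sequence":
            frames = frames[::-1].copy()
            thyroid = thyroid[::-1].copy()
            lesion = lesion[::-1].copy()
    return frames, thyroid, lesion


# ---------------------------------------------------------------------------
# stage plans


@dataclass
class StagePlan:
    stage: int
    data_source: str = "train_set"  # 'pretrain_set' | 'train_set'
    sequence_mode: str = "frames"  # 'frames' | 'full_sequences'
    frozen_scope: str = "none"  # 'none' | 'up_to_aspp' | 'backbone_all'
    scheme: AugmentationScheme = field(default_factory=lambda: default_schemes()[1])
    sampler_policy: str = "uniform"  # 'uniform' | 'forced_nodule' | 'subsample' | 'duplicate'
    forced_nodule_ratio: float = 2.0 / 3.0
    epochs: int = 4
    steps_per_epoch: int = 20
    batch_size: int = 6
    learning_rate: float = 1e-3
    lr_decay: float = 1.0  # multiplicative per-epoch decay
    optimizer_name: str = "adam"
    seed: int = 0


def default_stage_plans(seed: int = 0) -> dict[int, StagePlan]:
    """Desk-size defaults for the four stages (epoch counts kept small)."""
    schemes = default_schemes()
    return {
        1: StagePlan(1, data_source="pretrain_set", scheme=schemes[1],
                     epochs=12, steps_per_epoch=20, batch_size=6,
                     learning_rate=1e-3, seed=seed),
        2: StagePlan(2, data_source="train_set", scheme=schemes[2],
                     sampler_policy="forced_nodule", forced_nodule_ratio=2 / 3,
                     epochs=10, steps_per_epoch=20, batch_size=6,
                     learning_rate=1e-3, seed=seed + 1),
        3: StagePlan(3, data_source="train_set", sequence_mode="full_sequences",
                     frozen_scope="up_to_aspp", scheme=schemes[3],
                     epochs=3, steps_per_epoch=10, batch_size=1,
                     learning_rate=1e-4, seed=seed + 2),
        4: StagePlan(4, data_source="train_set", sequence_mode="full_sequences",
                     frozen_scope="backbone_all", scheme=schemes[4],
                     sampler_policy="forced_nodule", forced_nodule_ratio=0.5,
                     epochs=40, steps_per_epoch=14, batch_size=1,
                     learning_rate=2e-3, lr_decay=0.94, seed=seed + 3),
    }


@dataclass
class TrainState:
    """Checkpoint chain of the protocol: config plus the current models."""

    config: ModelConfig
    stage_completed: int = 0
    static_model: StaticModel | None = None
    recurrent_model: RecurrentModel | None = None
    class_weights: ClassWeights | None = None


def cohort_from_manifest(clips: Sequence[tuple[CineClip, MaskStack]],
                         manifest: DatasetManifest) -> dict[str, list]:
    """Group (clip, masks) pairs by manifest split.

    The pre-training set is the training set plus any records explicitly
    marked ``pretrain`` (clips where only the thyroid was annotated).
    """
    if len(clips) != len(manifest.records):
        raise ValueError("clips and manifest records are misaligned")
    out: dict[str, list] = {k: [] for k in ("pretrain", "train", "validation", "test")}
    for pair, rec in zip(clips, manifest.records):
        if rec.split in out:
            out[rec.split].append(pair)
    out["pretrain"] = out["train"] + out["pretrain"]
    return out


class _Lesionless:
    """Adapter presenting thyroid-only truth to the dual-format loss."""

    def __init__(self, thyroid):
        self.thyroid = thyroid
        self.lesion = np.zeros_like(thyroid, dtype=np.uint8)


def _select_data(plan: StagePlan, cohort: dict[str, list]):
    if plan.data_source == "pretrain_set":
        data = cohort.get("pretrain") or []
        if not data:
            warnings.warn("pre-training split empty; falling back to the training set",
                          stacklevel=2)
            data = cohort["train"]
    else:
        data = cohort["train"]
    if not data:
        raise ValueError(f"no data available for stage {plan.stage}")
    return data


def _frame_batches(plan: StagePlan, data, rng):
    """Yield (frames, thyroid, lesion) frame batches per the sampler policy."""
    masks = [m for _, m in data]
    if plan.sampler_policy == "uniform":
        refs_iter = sample_training_batches(masks, plan.batch_size, 0.0, rng,
                                            policy="forced_nodule")
    else:
        refs_iter = sample_training_batches(masks, plan.batch_size,
                                            plan.forced_nodule_ratio, rng,
                                            policy=plan.sampler_policy)
    for refs, _forced in refs_iter:
        fr = np.stack([data[r.clip_index][0].frames[r.frame_index] for r in refs])
        th = np.stack([data[r.clip_index][1].thyroid[r.frame_index] for r in refs])
        le = np.stack([data[r.clip_index][1].lesion[r.frame_index] for r in refs])
        yield fr, th, le


def _window_batch(plan: StagePlan, data, window: int, rng):
    """One window of consecutive frames, preferring nodule-bearing clips."""
    if plan.sampler_policy == "forced_nodule" and rng.random() < plan.forced_nodule_ratio:
        pool = [i for i, (_, m) in enumerate(data) if (m.lesion == 2).any()] or list(
            range(len(data))
        )
    else:
        pool = list(range(len(data)))
    ci = pool[int(rng.integers(len(pool)))]
    clip, masks = data[ci]
    t = clip.n_frames
    if t <= window:
        sel = np.clip(np.arange(window), 0, t - 1)
    else:
        nod_frames = np.flatnonzero((masks.lesion == 2).any(axis=(1, 2)))
        if plan.sampler_policy == "forced_nodule" and nod_frames.size and rng.random() < plan.forced_nodule_ratio:
            center = int(nod_frames[rng.integers(nod_frames.size)])
            start = int(np.clip(center - window // 2, 0, t - window))
        else:
            start = int(rng.integers(0, t - window + 1))
        sel = np.arange(start, start + window)
    return clip.frames[sel], masks.thyroid[sel], masks.lesion[sel]


def _loss_for(model, frames, thyroid, lesion, weights, stage):
    x = Tensor(frames[:, None].astype(np.float32))
    out = model(x)
    if stage == 1:
        truth = _Lesionless(thyroid)
        out = replace(out, lesion_prob=None) if out.lesion_prob is not None else out
    else:
        truth = MaskStack(thyroid, lesion)
    return mcc_loss(out, truth, weights)


def run_stage(plan: StagePlan, state: TrainState, cohort: dict[str, list]
              ) -> tuple[TrainState, list[dict]]:
    """Train one stage; returns the advanced state and per-epoch history."""
    if plan.stage not in (1, 2, 3, 4):
        raise ValueError("stage must be 1..4")
    if plan.stage > state.stage_completed + 1:
        raise ValueError(
            f"stage {plan.stage} requires a checkpoint from stage {plan.stage - 1}; "
            f"state has completed stage {state.stage_completed}"
        )
    config = state.config
    rng = np.random.default_rng(plan.seed)
    data = _select_data(plan, cohort)

    # majority down-weighting only: up-weighting minorities by inverse pixel
    # frequency on top of it destabilises training and over-segments
    if state.class_weights is None and plan.stage >= 2:
        state.class_weights = ClassWeights()
    weights = state.class_weights if plan.stage >= 2 else ClassWeights()

    if plan.stage == 1:
        model = build_static_model(config, 1, seed=plan.seed)
        state.static_model = model
    elif plan.stage == 2:
        model = build_static_model(config, 2, seed=plan.seed)
        if state.static_model is not None:
            model.load_state_dict(state.static_model.state_dict(), strict=False)
        state.static_model = model
    elif plan.stage == 3:
        model = state.static_model
        if model is None or model.stage != 2:
            raise ValueError("stage 3 requires the dual-output model from stage 2")
        model.freeze_through_aspp()
    else:
        if state.static_model is None or state.static_model.stage != 2:
            raise ValueError("stage 4 requires the dual-output model from stage 2/3")
        model = build_recurrent_model(config, state.static_model, seed=plan.seed)
        state.recurrent_model = model

    model.train()
    params = [p for p in model.parameters() if p.requires_grad]
    opt = Adam(params, lr=plan.learning_rate)
    window = config.window
    history: list[dict] = []
    for _epoch in range(plan.epochs):
        opt.lr = plan.learning_rate * plan.lr_decay**_epoch
        losses = []
        if plan.sequence_mode == "frames":
            batches = _frame_batches(plan, data, rng)
        for _step in range(plan.steps_per_epoch):
            if plan.sequence_mode == "frames":
                fr, th, le = next(batches)
            elif plan.stage == 4:
                fr, th, le = _window_batch(plan, data, window, rng)
            else:  # full sequences through the static model
                ci = int(rng.integers(len(data)))
                clip, masks = data[ci]
                fr, th, le = clip.frames, masks.thyroid, masks.lesion
            fr, th, le = augment(fr, th, le, plan.scheme, rng,
                                 sequence_mode=plan.sequence_mode == "full_sequences")
            opt.zero_grad()
            loss = _loss_for(model, fr, th, le, weights, plan.stage)
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.append({"stage": plan.stage, "loss": float(np.mean(losses))})
    state.stage_completed = max(state.stage_completed, plan.stage)
    model.eval()
    return state, history


def run_full_protocol(config: ModelConfig, cohort: dict[str, list], seed: int = 0,
                      stages: Sequence[int] = (1, 2, 3, 4),
                      plans: dict[int, StagePlan] | None = None
                      ) -> tuple[TrainState, dict[int, list[dict]]]:
    """Chain the training stages, passing checkpoints along."""
    plans = plans or default_stage_plans(seed)
    state = TrainState(config=config)
    histories: dict[int, list[dict]] = {}
    for stage in stages:
        try:
            state, hist = run_stage(plans[stage], state, cohort)
        except Exception as exc:
            raise RuntimeError(f"training stage {stage} failed: {exc}") from exc
        histories[stage] = hist
    return state, histories


def evaluate_model(model, data: Sequence[tuple[CineClip, MaskStack]],
                   classes: Sequence[str] = ("thyroid", "cyst", "nodule")
                   ) -> dict[str, dict[str, float]]:
    """Mean per-clip metrics of a model over (clip, masks) pairs."""
    per_clip: dict[str, list] = {c: [] for c in classes}
    for clip, masks in data:
        seg = segment_cineclip(model, clip)
        thy, les = harden(seg)
        metrics = per_class_metrics(thy, les, masks)
        for c in classes:
            per_clip[c].append(metrics[c])
    out: dict[str, dict[str, float]] = {}
    for c, sets in per_clip.items():
        out[c] = {
            k: float(np.mean([m.as_dict()[k] for m in sets])) for k in
            ("iou", "mcc", "recall", "precision", "f2")
        }
    return out
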