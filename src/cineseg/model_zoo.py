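"""Static and recurrent segmentation models.

The static model is a DeepLab-style encoder: a three-convolution input stem
(ResNet-C replacement), four residual bottleneck stages where the last two
trade striding for dilation (rates 2 and 4, output stride 8), an atrous
spatial pyramid pooling (ASPP) module, and four skip-fusion steps (each
skip and the main path pass through 1×1 convolutions, are concatenated,
batch-normalized and LeakyReLU-activated).  Two upsampling heads restore
input resolution: a sigmoid head for the thyroid and a 3-channel softmax
head for background/cyst/nodule — the dual-output formulation that lets a
lesion overlap the organ without carving holes in the organ mask.

The recurrent model freezes a pretrained static encoder, replicates it over
a 6-frame window (two groups of three), and replaces the upsampling layers
with a recurrent module: per group, four blocks of paired forward/backward
convolutional LSTMs at dilations 1, 3, 5, 7 (concat + BN + LeakyReLU after
each pair), then one final forward and one final backward ConvLSTM over the
merged 6-step sequence, concatenated and fed to the dual heads.  That is
2 groups × 4 blocks × 2 + 2 = 18 ConvLSTM layers at the default
configuration.

All filter counts scale with ``width_multiplier`` (ceil of table value ×
multiplier) so desk-size instantiations preserve the architecture.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .cine_io import CineClip, PAD_VALUE
from .nn import (
    BatchNorm2d,
    BidirectionalConvLSTMBlock,
    Conv2d,
    ConvLSTM2d,
    ConvTranspose2d,
    Module,
    Tensor,
    bilinear_resize,
    concat,
    max_pool2d,
)

__all__ = [
    "ModelConfig",
    "SegOutput",
    "Backbone",
    "StaticModel",
    "RecurrentModel",
    "build_backbone",
    "build_static_model",
    "build_recurrent_model",
    "segment_cineclip",
    "count_convlstm_layers",
    "parameter_count",
    "conv_core_parameter_count",
    "tiny_config",
    "save_checkpoint",
    "load_checkpoint",
]

# (reduce, inner, expand) widths and per-stage (stride, dilation) at width 1
_STAGE_WIDTHS = ((64, 64, 256), (128, 128, 512), (256, 256, 1024), (512, 512, 2048))
_STAGE_STRIDE_DILATION = ((1, 1), (2, 1), (1, 2), (1, 4))


@dataclass
class ModelConfig:
    """Width/depth/window/dilation parameterisation of the models."""

    input_size: tuple[int, int] = (256, 256)
    width_multiplier: float = 1.0
    block_counts: tuple[int, int, int, int] = (2, 4, 23, 2)
    leaky_alpha: float = 0.10
    output_stride: int = 8
    aspp_dilations: tuple[int, ...] = (6, 12, 18)
    aspp_filters: int = 256
    fusion_filters: int = 128
    recurrent_filters: int = 32
    recurrent_kernel: tuple[int, int] = (3, 3)
    recurrent_dilations: tuple[int, ...] = (1, 3, 5, 7)
    window: int = 6
    lesion_classes: int = 3
    upsample_head: str = "fullcover"  # 'fullcover' | 'prose' | 'table8'

    def __post_init__(self):
        if self.width_multiplier * 32 < 1:
            raise ValueError("width_multiplier too small (width·32 must be ≥ 1)")
        if self.window < 2 or self.window % 2:
            raise ValueError("window must be even and ≥ 2")
        if self.output_stride not in (8, 16):
            raise ValueError("output_stride must be 8 or 16")
        if self.upsample_head not in ("fullcover", "prose", "table8"):
            raise ValueError(f"unknown upsample_head {self.upsample_head!r}")

    def scaled(self, filters: int) -> int:
        return max(1, math.ceil(filters * self.width_multiplier))

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        raw = json.loads(text)
        for key in ("input_size", "block_counts", "aspp_dilations",
                    "recurrent_kernel", "recurrent_dilations"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def tiny_config(canvas: int = 64, width: float = 1 / 8,
                block_counts: tuple[int, int, int, int] = (1, 1, 2, 1),
                recurrent_filters: int = 16) -> ModelConfig:
    """A desk-size instantiation: narrow, shallow, small canvas.

    Depth is reduced along with width; the stage structure, dilation scheme,
    ASPP, fusion and recurrent topology are unchanged.
    """
    return ModelConfig(
        input_size=(canvas, canvas),
        width_multiplier=width,
        block_counts=block_counts,
        aspp_dilations=(2, 4, 6),
        recurrent_filters=recurrent_filters,
    )


@dataclass
class SegOutput:
    """Dual-head prediction: sigmoid thyroid map + softmax lesion map."""

    thyroid_prob: object  # T×H×W (Tensor or ndarray)
    lesion_prob: object | None = None  # T×3×H×W, softmax over axis 1

    def numpy(self) -> "SegOutput":
        thy = self.thyroid_prob.data if isinstance(self.thyroid_prob, Tensor) else self.thyroid_prob
        les = self.lesion_prob
        if isinstance(les, Tensor):
            les = les.data
        return SegOutput(np.asarray(thy), None if les is None else np.asarray(les))


class _Bottleneck(Module):
    """Residual bottleneck (1×1 reduce, 3×3, 1×1 expand) per the block table."""

    def __init__(self, in_ch, widths, *, stride=1, dilation=1, projection=False,
                 alpha=0.10, rng=None):
        super().__init__()
        x, y, z = widths
        self.alpha = alpha
        self.conv1 = Conv2d(in_ch, x, 1, rng=rng, bias=False)
        self.bn1 = BatchNorm2d(x)
        self.conv2 = Conv2d(x, y, 3, stride=stride, dilation=dilation,
                            padding=dilation, rng=rng, bias=False)
        self.bn2 = BatchNorm2d(y)
        self.conv3 = Conv2d(y, z, 1, rng=rng, bias=False)
        self.bn3 = BatchNorm2d(z)
        if projection:
            self.proj = Conv2d(in_ch, z, 1, stride=stride, rng=rng, bias=False)
            self.proj_bn = BatchNorm2d(z)
        else:
            self.proj = None

    def forward(self, x):
        a = self.bn1(self.conv1(x)).leaky_relu(self.alpha)
        a = self.bn2(self.conv2(a)).leaky_relu(self.alpha)
        a = self.bn3(self.conv3(a))
        if self.proj is not None:
            shortcut = self.proj_bn(self.proj(x))
        else:
            shortcut = x
            a = a.leaky_relu(self.alpha)  # identity blocks activate pre-add
        return (a + shortcut).leaky_relu(self.alpha)


class _ASPP(Module):
    """Atrous spatial pyramid pooling: 1×1, dilated 3×3s, image pooling."""

    def __init__(self, in_ch, filters, dilations, alpha, rng):
        super().__init__()
        self.alpha = alpha
        self.branches = []
        self.branch_bns = []
        self.branches.append(Conv2d(in_ch, filters, 1, rng=rng, bias=False))
        self.branch_bns.append(BatchNorm2d(filters))
        for d in dilations:
            self.branches.append(
                Conv2d(in_ch, filters, 3, dilation=d, padding=d, rng=rng, bias=False)
            )
            self.branch_bns.append(BatchNorm2d(filters))
        self.pool_conv = Conv2d(in_ch, filters, 1, rng=rng, bias=False)
        self.pool_bn = BatchNorm2d(filters)
        n = len(self.branches) + 1
        self.project = Conv2d(n * filters, filters, 1, rng=rng, bias=False)
        self.project_bn = BatchNorm2d(filters)

    def forward(self, x):
        outs = [
            bn(conv(x)).leaky_relu(self.alpha)
            for conv, bn in zip(self.branches, self.branch_bns)
        ]
        pooled = x.mean(axis=(2, 3), keepdims=True)
        pooled = self.pool_bn(self.pool_conv(pooled)).leaky_relu(self.alpha)
        ones = Tensor(np.ones((1, 1) + x.shape[2:], dtype=np.float32))
        outs.append(pooled * ones)  # broadcast back to the feature size
        y = concat(outs, axis=1)
        return self.project_bn(self.project(y)).leaky_relu(self.alpha)


class _SkipFusion(Module):
    """1×1-convolve skip and main path, concat, BN, LeakyReLU."""

    def __init__(self, skip_ch, main_ch, filters, alpha, rng):
        super().__init__()
        self.skip_conv = Conv2d(skip_ch, filters, 1, rng=rng, bias=False)
        self.main_conv = Conv2d(main_ch, filters, 1, rng=rng, bias=False)
        self.bn = BatchNorm2d(2 * filters)
        self.alpha = alpha

    def forward(self, main, skip):
        skip = bilinear_resize(skip, main.shape[2:])
        y = concat([self.main_conv(main), self.skip_conv(skip)], axis=1)
        return self.bn(y).leaky_relu(self.alpha)


class Backbone(Module):
    """Stem + residual stages + ASPP + skip fusion → one fused feature map."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        c = config
        self.config = config
        a = c.leaky_alpha
        s32, s64 = c.scaled(32), c.scaled(64)
        self.stem1 = Conv2d(1, s32, 3, stride=2, padding=1, rng=rng, bias=False)
        self.stem_bn1 = BatchNorm2d(s32)
        self.stem2 = Conv2d(s32, s32, 3, rng=rng, bias=False)
        self.stem_bn2 = BatchNorm2d(s32)
        self.stem3 = Conv2d(s32, s64, 3, rng=rng, bias=False)
        self.stem_bn3 = BatchNorm2d(s64)

        self.stages = []
        in_ch = s64
        skip_channels = [s64]  # Skip1: the maxpool output
        for (widths, (stride, dilation), repeats) in zip(
            _STAGE_WIDTHS, _STAGE_STRIDE_DILATION, c.block_counts
        ):
            if c.output_stride == 16 and dilation == 2:
                stride, dilation = 2, 1  # keep striding one stage longer
            w = tuple(c.scaled(v) for v in widths)
            blocks = [
                _Bottleneck(in_ch, w, stride=stride, dilation=dilation,
                            projection=True, alpha=a, rng=rng)
            ]
            for _ in range(repeats):
                blocks.append(
                    _Bottleneck(w[2], w, stride=1, dilation=dilation,
                                projection=False, alpha=a, rng=rng)
                )
            self.stages.append(blocks)
            in_ch = w[2]
            skip_channels.append(in_ch)

        self.aspp = _ASPP(in_ch, c.scaled(c.aspp_filters), c.aspp_dilations, a, rng)
        ff = c.scaled(c.fusion_filters)
        main_ch = c.scaled(c.aspp_filters)
        self.fusions = []
        for skip_ch in skip_channels[:4]:  # Skip1..Skip4
            self.fusions.append(_SkipFusion(skip_ch, main_ch, ff, a, rng))
            main_ch = 2 * ff
        self.out_channels = main_ch

    def forward(self, x: Tensor) -> Tensor:
        a = self.config.leaky_alpha
        y = self.stem_bn1(self.stem1(x)).leaky_relu(a)
        y = self.stem_bn2(self.stem2(y)).leaky_relu(a)
        y = self.stem_bn3(self.stem3(y)).leaky_relu(a)
        y = max_pool2d(y, 3, 2, 1)
        skips = [y]
        for blocks in self.stages:
            for block in blocks:
                y = block(y)
            skips.append(y)
        y = self.aspp(y)
        for fusion, skip in zip(self.fusions, skips[:4]):
            y = fusion(y, skip)
        return y


class _UpsampleHead(Module):
    """Transposed-convolution head restoring input resolution (×8).

    ``fullcover`` (default): DC k8 s4 p2 then DC k4 s2 p1 — exact ×8 with
    every output pixel covered.  ``prose``: a single DC k4 s8 (stride >
    kernel leaves uncovered stripes; kept for fidelity to the described
    variant).  ``table8``: a single DC k8 s4 followed by bilinear ×2.
    """

    def __init__(self, in_ch, n_out, mode, rng):
        super().__init__()
        self.mode = mode
        if mode == "fullcover":
            self.dc1 = ConvTranspose2d(in_ch, n_out, 8, stride=4, padding=2, rng=rng)
            self.dc2 = ConvTranspose2d(n_out, n_out, 4, stride=2, padding=1, rng=rng)
        elif mode == "prose":
            self.dc1 = ConvTranspose2d(in_ch, n_out, 4, stride=8,
                                       output_padding=4, rng=rng)
            self.dc2 = None
        else:  # table8
            self.dc1 = ConvTranspose2d(in_ch, n_out, 8, stride=4, padding=2, rng=rng)
            self.dc2 = None
        self.final = Conv2d(n_out, n_out, 1, rng=rng)

    def forward(self, x, out_hw):
        y = self.dc1(x)
        if self.mode == "fullcover":
            y = self.dc2(y)
        elif self.mode == "table8":
            y = bilinear_resize(y, (y.shape[2] * 2, y.shape[3] * 2))
        y = bilinear_resize(y, out_hw) if y.shape[2:] != tuple(out_hw) else y
        return self.final(y)


class StaticModel(Module):
    """Stage-1 (thyroid only) or stage-2/3 (dual output) frame model."""

    def __init__(self, config: ModelConfig, stage: int, rng: np.random.Generator):
        super().__init__()
        if stage not in (1, 2):
            raise ValueError("static model stage must be 1 or 2")
        self.config = config
        self.stage = stage
        self.backbone = Backbone(config, rng)
        ch = self.backbone.out_channels
        self.thyroid_head = _UpsampleHead(ch, 1, config.upsample_head, rng)
        self.lesion_head = (
            _UpsampleHead(ch, config.lesion_classes, config.upsample_head, rng)
            if stage == 2
            else None
        )

    def forward(self, frames: Tensor) -> SegOutput:
        x, orig_hw = _pad_to_stride(frames, self.config.output_stride)
        fused = self.backbone(x)
        hw = x.shape[2:]
        thy = self.thyroid_head(fused, hw).sigmoid()
        thy = _crop(thy, orig_hw)
        lesion = None
        if self.lesion_head is not None:
            lesion = self.lesion_head(fused, hw).softmax(axis=1)
            lesion = _crop(lesion, orig_hw)
        return SegOutput(thy, lesion)

    def freeze_through_aspp(self):
        """Freeze stem, residual stages and ASPP; fusion + heads stay trainable."""
        for name, p in self.named_parameters():
            p.requires_grad = not name.startswith(
                ("backbone.stem", "backbone.stages", "backbone.aspp")
            )
        return self


def _pad_to_stride(frames: Tensor, stride: int):
    n, c, h, w = frames.shape
    hp = (stride - h % stride) % stride
    wp = (stride - w % stride) % stride
    if hp == 0 and wp == 0:
        return frames, (h, w)
    canvas = np.full((n, c, h + hp, w + wp), PAD_VALUE, dtype=np.float32)
    canvas[:, :, :h, :w] = frames.data
    out = Tensor(canvas)
    out.requires_grad = frames.requires_grad
    return out, (h, w)


def _crop(x: Tensor, hw):
    if x.shape[2:] == tuple(hw):
        return x
    return x[:, :, : hw[0], : hw[1]]


class RecurrentModel(Module):
    """Frozen backbone replicas + bidirectional dilated ConvLSTM module."""

    def __init__(self, config: ModelConfig, backbone: Backbone,
                 rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.backbone = backbone  # shared, frozen weights for all replicas
        self.backbone.freeze(True)
        self.backbone.eval()
        ch = backbone.out_channels
        f = config.recurrent_filters
        k = config.recurrent_kernel[0]
        a = config.leaky_alpha
        self.forward_group = _recurrent_stack(ch, f, k, config.recurrent_dilations, a, rng)
        self.backward_group = _recurrent_stack(ch, f, k, config.recurrent_dilations, a, rng)
        self.final_fwd = ConvLSTM2d(2 * f, f, k, dilation=1, rng=rng)
        self.final_bwd = ConvLSTM2d(2 * f, f, k, dilation=1, rng=rng)
        self.final_bn = BatchNorm2d(2 * f, track_running_stats=False)
        self.thyroid_head = _UpsampleHead(2 * f, 1, config.upsample_head, rng)
        self.lesion_head = _UpsampleHead(2 * f, config.lesion_classes,
                                         config.upsample_head, rng)

    def forward(self, frames: Tensor) -> SegOutput:
        """Segment a window of ``config.window`` frames (T,1,H,W) jointly."""
        t = frames.shape[0]
        if t != self.config.window:
            raise ValueError(f"expected a window of {self.config.window} frames, got {t}")
        x, orig_hw = _pad_to_stride(frames, self.config.output_stride)
        hw = x.shape[2:]
        self.backbone.eval()  # frozen replicas always run with running stats
        fused = self.backbone(x)  # one batched pass over all replicas
        feats = [fused[i : i + 1] for i in range(t)]
        half = t // 2
        seq_f = feats[:half]
        seq_b = feats[half:]
        for block in self.forward_group:
            seq_f = block(seq_f)
        for block in self.backward_group:
            seq_b = block(seq_b)
        merged = seq_f + seq_b  # 6-step sequence in frame order
        out_f = self.final_fwd(merged, reverse=False)
        out_b = self.final_bwd(merged, reverse=True)
        a = self.config.leaky_alpha
        steps = [
            self.final_bn(concat([f_, b_], axis=1)).leaky_relu(a)
            for f_, b_ in zip(out_f, out_b)
        ]
        y = concat(steps, axis=0)  # (T, 2f, h, w)
        thy = _crop(self.thyroid_head(y, hw).sigmoid(), orig_hw)
        lesion = _crop(self.lesion_head(y, hw).softmax(axis=1), orig_hw)
        return SegOutput(thy, lesion)

    def train(self, mode: bool = True):
        super().train(mode)
        self.backbone.eval()  # replicas stay frozen in inference mode
        return self


def _recurrent_stack(in_ch, filters, kernel, dilations, alpha, rng):
    blocks = []
    ch = in_ch
    for d in dilations:
        blocks.append(
            BidirectionalConvLSTMBlock(ch, filters, kernel, dilation=d,
                                       leaky_alpha=alpha, rng=rng)
        )
        ch = 2 * filters
    return blocks


# ---------------------------------------------------------------------------
# builders


def build_backbone(config: ModelConfig, seed: int = 0) -> Backbone:
    return Backbone(config, np.random.default_rng(seed))


def build_static_model(config: ModelConfig, stage: int, seed: int = 0) -> StaticModel:
    return StaticModel(config, stage, np.random.default_rng(seed))


def build_recurrent_model(config: ModelConfig, pretrained_static: StaticModel,
                          seed: int = 0) -> RecurrentModel:
    """Adapt a pretrained static model into the windowed recurrent model.

    The static encoder's weights are shared (not copied) across the window's
    replicas and frozen; the recurrent module and new heads are trainable.
    """
    if pretrained_static.config.width_multiplier != config.width_multiplier:
        raise ValueError("recurrent model must reuse the pretrained config width")
    return RecurrentModel(config, pretrained_static.backbone,
                          np.random.default_rng(seed))


def count_convlstm_layers(model: Module) -> list[ConvLSTM2d]:
    return [m for m in model.modules() if isinstance(m, ConvLSTM2d)]


def parameter_count(model: Module, trainable_only: bool = False) -> int:
    return sum(
        p.data.size
        for p in model.parameters()
        if (p.requires_grad or not trainable_only)
    )


def conv_core_parameter_count(backbone: Backbone) -> int:
    """Parameters of the residual-stage convolutions (the width-scaling core)."""
    total = 0
    for blocks in backbone.stages:
        for block in blocks:
            for name, p in block.named_parameters():
                if "conv" in name or "proj" in name:
                    total += p.data.size
    return total


# ---------------------------------------------------------------------------
# inference over whole clips


def segment_cineclip(model: Module, clip: CineClip, window: int | None = None,
                     stride: int | None = None, batch_size: int = 8) -> SegOutput:
    """Run a model over all frames of a clip and assemble one SegOutput.

    Static models run frame-wise (batched).  Recurrent models run a sliding
    window with edge replication for clips shorter than the window; window
    predictions cover all window frames and overlapping windows are
    averaged.
    """
    frames = clip.frames[:, None]  # (T,1,H,W)
    t = frames.shape[0]
    model.eval()
    if isinstance(model, StaticModel):
        thy_parts, les_parts = [], []
        for lo in range(0, t, batch_size):
            out = model(Tensor(frames[lo : lo + batch_size]))
            out = out.numpy()
            thy_parts.append(out.thyroid_prob[:, 0])
            if out.lesion_prob is not None:
                les_parts.append(out.lesion_prob)
        thy = np.concatenate(thy_parts)
        les = np.concatenate(les_parts) if les_parts else None
        return SegOutput(thy, les)

    window = window or model.config.window
    stride = stride or max(window // 2, 1)
    idx = np.arange(t)
    if t < window:  # edge replication for very short clips
        idx = np.concatenate([idx, np.full(window - t, t - 1)])
    else:
        # reflect-pad so every real frame also occupies interior window
        # positions (edge positions of a window carry less temporal context)
        pad = window // 2
        idx = np.pad(idx, pad, mode="reflect" if t > 1 else "edge")
    starts = list(range(0, len(idx) - window + 1, stride))
    if starts[-1] != len(idx) - window:
        starts.append(len(idx) - window)
    h, w = frames.shape[2:]
    thy_sum = np.zeros((t, h, w), np.float64)
    les_sum = np.zeros((t, model.config.lesion_classes, h, w), np.float64)
    counts = np.zeros(t, np.int64)
    for s in starts:
        sel = idx[s : s + window]
        # average both temporal orientations; sequence reversal is part of
        # the sequence-stage augmentation, so reversed windows are
        # in-distribution and the ensemble symmetrizes boundary quality
        for order in (slice(None), slice(None, None, -1)):
            out = model(Tensor(frames[sel][order])).numpy()
            for k, fi in enumerate(sel[order]):
                thy_sum[fi] += out.thyroid_prob[k, 0]
                les_sum[fi] += out.lesion_prob[k]
                counts[fi] += 1
    counts = np.maximum(counts, 1)
    thy = (thy_sum / counts[:, None, None]).astype(np.float32)
    les = (les_sum / counts[:, None, None, None]).astype(np.float32)
    les /= les.sum(axis=1, keepdims=True)  # keep the softmax simplex exact
    return SegOutput(thy, les)


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(path: str | Path, model: Module, config: ModelConfig,
                    extra: dict | None = None) -> None:
    """Save weights as an .npz plus a JSON sidecar of the ModelConfig."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    meta = {"config": json.loads(config.to_json())}
    if extra:
        meta.update(extra)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path: str | Path, model: Module) -> ModelConfig:
    path = Path(path)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
        model.load_state_dict({k: data[k] for k in data.files}, strict=False)
    meta = json.loads(path.with_suffix(".json").read_text())
    return ModelConfig.from_json(json.dumps(meta["config"]))
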