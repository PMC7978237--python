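"""Cineclip, mask and manifest I/O plus dataset preprocessing.

A *cineclip* is a transverse sweep of the thyroid recorded as a stack of
grayscale B-mode frames.  Preprocessing resizes every frame so its largest
dimension equals a target (256 by default), preserving aspect ratio, and
fills the unused canvas with the sentinel value −1 so the models can tell
genuinely dark tissue from filler.  Ground truth is stored as two parallel
layers per frame: a binary thyroid layer and an exclusive lesion layer
(0 background, 1 cyst, 2 nodule); lesions may extend outside the thyroid
layer — no containment is enforced, matching the dual-output formulation.

On disk: frames are float32 multi-page TIFF, the two mask layers are uint8
multi-page TIFFs, and the dataset manifest is JSON.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import tifffile
from skimage.transform import resize as _sk_resize

__all__ = [
    "PAD_VALUE",
    "CineClip",
    "MaskStack",
    "ManifestRecord",
    "DatasetManifest",
    "resize_with_padding",
    "preprocess_clip",
    "split_by_patient",
    "sample_training_batches",
    "read_cineclip",
    "write_cineclip",
    "read_masks",
    "write_masks",
    "read_manifest",
    "write_manifest",
]

PAD_VALUE = -1.0

SIDES = ("left", "right", "unknown")
ECHOGENICITIES = ("hypo", "iso", "hyper", "none")
MARGINS = ("smooth", "ill-defined", "lobulated", "none")
MALIGNANCIES = ("benign", "malignant", "none")
SPLITS = ("pretrain", "train", "validation", "test", "unassigned")
EXCLUSIVE_SPLITS = ("train", "validation", "test")


@dataclass
class CineClip:
    """A T×H×W grayscale frame stack with sentinel padding and metadata."""

    frames: np.ndarray
    patient_id: str
    side: str = "unknown"
    source_shape: tuple[int, int] | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError(f"frames must be T×H×W with T ≥ 1, got {self.frames.shape}")
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}")
        self.validate()

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def validate(self) -> None:
        tissue = self.frames[self.frames != PAD_VALUE]
        if tissue.size and (tissue.min() < 0.0 or tissue.max() > 1.0):
            raise ValueError(
                "tissue intensities must lie in [0, 1] "
                f"(found range [{tissue.min():.4g}, {tissue.max():.4g}])"
            )


@dataclass
class MaskStack:
    """Two-layer ground truth: binary thyroid + exclusive lesion codes."""

    thyroid: np.ndarray
    lesion: np.ndarray

    def __post_init__(self):
        self.thyroid = np.asarray(self.thyroid, dtype=np.uint8)
        self.lesion = np.asarray(self.lesion, dtype=np.uint8)
        self.validate()

    def validate(self) -> None:
        if self.thyroid.shape != self.lesion.shape:
            raise ValueError(
                f"thyroid {self.thyroid.shape} and lesion {self.lesion.shape} "
                "layers must share one shape"
            )
        if self.thyroid.ndim != 3:
            raise ValueError(f"mask layers must be T×H×W, got {self.thyroid.shape}")
        if not np.isin(self.thyroid, (0, 1)).all():
            raise ValueError("thyroid layer must be binary")
        bad = np.setdiff1d(np.unique(self.lesion), (0, 1, 2))
        if bad.size:
            raise ValueError(f"illegal lesion codes {bad.tolist()} (allowed: 0, 1, 2)")

    def check_against(self, clip: CineClip) -> None:
        if self.thyroid.shape != clip.frames.shape:
            raise ValueError(
                f"mask shape {self.thyroid.shape} does not match "
                f"clip shape {clip.frames.shape}"
            )


@dataclass
class ManifestRecord:
    patient_id: str
    clip_path: str
    mask_path: str
    pathology: str = "unknown"
    n_pathology_cohort: int = 3
    echogenicity: str = "none"
    margins: str = "none"
    malignancy: str = "none"
    split: str = "unassigned"
    thin_test_frames: bool = False  # optional every-20th-frame thinning flag

    def __post_init__(self):
        if self.echogenicity not in ECHOGENICITIES:
            raise ValueError(f"echogenicity must be one of {ECHOGENICITIES}")
        if self.margins not in MARGINS:
            raise ValueError(f"margins must be one of {MARGINS}")
        if self.malignancy not in MALIGNANCIES:
            raise ValueError(f"malignancy must be one of {MALIGNANCIES}")
        if self.split not in SPLITS:
            raise ValueError(f"split must be one of {SPLITS}")


@dataclass
class DatasetManifest:
    records: list[ManifestRecord] = field(default_factory=list)

    def validate(self) -> None:
        seen: dict[str, str] = {}
        for rec in self.records:
            if rec.split in EXCLUSIVE_SPLITS:
                prev = seen.get(rec.patient_id)
                if prev is not None and prev != rec.split:
                    raise ValueError(
                        f"patient {rec.patient_id!r} appears in both "
                        f"{prev!r} and {rec.split!r}"
                    )
                seen[rec.patient_id] = rec.split
            if rec.n_pathology_cohort < 3 and rec.split in ("validation", "test"):
                raise ValueError(
                    f"rare-pathology patient {rec.patient_id!r} "
                    f"(cohort {rec.n_pathology_cohort}) must not be in {rec.split!r}"
                )

    def by_split(self, split: str) -> list[ManifestRecord]:
        return [r for r in self.records if r.split == split]

    def patients(self) -> list[str]:
        out, seen = [], set()
        for r in self.records:
            if r.patient_id not in seen:
                seen.add(r.patient_id)
                out.append(r.patient_id)
        return out


# ---------------------------------------------------------------------------
# preprocessing


def resize_with_padding(image: np.ndarray, target: int, *,
                        is_mask: bool = False) -> tuple[np.ndarray, float]:
    """Resize so the largest dimension equals ``target``; pad with −1.

    The image is placed in the top-left corner of a ``target×target`` canvas;
    the remaining canvas is filled with the sentinel −1.  Frames are resized
    bilinearly and rescaled to [0, 1] if they exceed that range; masks use
    nearest-neighbour so labels stay label-valued (and are returned without
    intensity rescaling, padded with 0).

    Returns the padded canvas and the scale factor applied.
    """
    image = np.asarray(image)
    if image.ndim != 2 or image.size == 0:
        raise ValueError(f"expected a non-empty 2-D image, got shape {image.shape}")
    if target < 2:
        raise ValueError("target must be ≥ 2")
    h0, w0 = image.shape
    scale = target / max(h0, w0)
    if h0 >= w0:
        h, w = target, int(round(w0 * target / h0))
    else:
        h, w = int(round(h0 * target / w0)), target
    h, w = max(h, 1), max(w, 1)
    if is_mask:
        tissue = _sk_resize(image, (h, w), order=0, preserve_range=True,
                            anti_aliasing=False).astype(image.dtype)
        canvas = np.zeros((target, target), dtype=image.dtype)
        canvas[:h, :w] = tissue
        return canvas, scale
    img = image.astype(np.float32)
    lo, hi = float(img.min()), float(img.max())
    if lo < 0.0 or hi > 1.0:
        img = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    tissue = _sk_resize(img, (h, w), order=1, preserve_range=True,
                        anti_aliasing=(scale < 1.0))
    tissue = np.clip(tissue, 0.0, 1.0).astype(np.float32)
    canvas = np.full((target, target), PAD_VALUE, dtype=np.float32)
    canvas[:h, :w] = tissue
    return canvas, scale


def preprocess_clip(clip: CineClip, masks: MaskStack | None, target: int = 256
                    ) -> tuple[CineClip, MaskStack | None]:
    """Apply :func:`resize_with_padding` to every frame (and mask plane).

    Intensity rescaling uses the global clip range so relative frame
    brightness is preserved across the sweep.
    """
    frames = np.asarray(clip.frames, np.float32)
    lo, hi = float(frames.min()), float(frames.max())
    if lo < 0.0 or hi > 1.0:
        frames = (frames - lo) / (hi - lo) if hi > lo else np.zeros_like(frames)
    out_frames = np.stack(
        [resize_with_padding(f, target)[0] for f in frames]
    )
    new_clip = CineClip(out_frames, clip.patient_id, clip.side,
                        source_shape=clip.frames.shape[1:])
    if masks is None:
        return new_clip, None
    thy = np.stack([resize_with_padding(m, target, is_mask=True)[0] for m in masks.thyroid])
    les = np.stack([resize_with_padding(m, target, is_mask=True)[0] for m in masks.lesion])
    return new_clip, MaskStack(thy, les)


# ---------------------------------------------------------------------------
# patient-wise splitting


def split_by_patient(manifest: DatasetManifest,
                     fractions: Sequence[float] | dict[str, float],
                     seed: int) -> DatasetManifest:
    """Assign patients to train/validation/test, stratified by pathology.

    Patients whose pathology cohort has fewer than three members are routed
    to the training set regardless of the seed; the remaining patients are
    shuffled within each pathology stratum and divided per ``fractions``
    (largest-remainder apportionment).  Records already marked ``pretrain``
    keep that split.  No patient straddles train/validation/test.
    """
    if isinstance(fractions, dict):
        fracs = (fractions["train"], fractions["validation"], fractions["test"])
    else:
        fracs = tuple(fractions)
    if len(fracs) != 3 or any(f < 0 for f in fracs):
        raise ValueError("fractions must be three non-negative numbers")
    if abs(sum(fracs) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fracs)}")
    if not manifest.records:
        raise ValueError("manifest is empty")

    # patient-level view (a patient may own several clips)
    info: dict[str, dict] = {}
    for rec in manifest.records:
        if rec.split == "pretrain":
            continue
        entry = info.setdefault(
            rec.patient_id,
            {"pathology": rec.pathology, "cohort": rec.n_pathology_cohort},
        )
        entry["cohort"] = min(entry["cohort"], rec.n_pathology_cohort)

    assignment: dict[str, str] = {}
    rare = sorted(p for p, e in info.items() if e["cohort"] < 3)
    for p in rare:
        assignment[p] = "train"

    strata: dict[str, list[str]] = {}
    for p in sorted(info):
        if p in assignment:
            continue
        strata.setdefault(info[p]["pathology"], []).append(p)

    rng = np.random.default_rng(seed)
    n_nonzero = sum(1 for f in fracs if f > 0)
    for pathology in sorted(strata):
        patients = strata[pathology]
        if len(patients) < n_nonzero:
            warnings.warn(
                f"pathology stratum {pathology!r} has only {len(patients)} "
                f"patient(s) for {n_nonzero} splits; assigning all to train",
                stacklevel=2,
            )
            for p in patients:
                assignment[p] = "train"
            continue
        order = rng.permutation(len(patients))
        shuffled = [patients[i] for i in order]
        n = len(shuffled)
        quotas = [f * n for f in fracs]
        counts = [int(q) for q in quotas]
        remainders = [q - c for q, c in zip(quotas, counts)]
        while sum(counts) < n:
            # favour the largest remainder; ties go to the earlier split
            k = int(np.argmax(remainders))
            counts[k] += 1
            remainders[k] = -1.0
        idx = 0
        for split_name, count in zip(EXCLUSIVE_SPLITS, counts):
            for p in shuffled[idx : idx + count]:
                assignment[p] = split_name
            idx += count

    new_records = []
    for rec in manifest.records:
        if rec.split == "pretrain":
            new_records.append(rec)
            continue
        new = ManifestRecord(**{**asdict(rec), "split": assignment[rec.patient_id]})
        new_records.append(new)
    out = DatasetManifest(new_records)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# batch sampling


@dataclass(frozen=True)
class FrameRef:
    """Index of one frame within a collection of clips."""

    clip_index: int
    frame_index: int


def _frame_pool(mask_stacks: Sequence[MaskStack]):
    all_frames, nodule_frames = [], []
    for ci, masks in enumerate(mask_stacks):
        nod = (masks.lesion == 2).any(axis=(1, 2))
        for fi in range(masks.lesion.shape[0]):
            ref = FrameRef(ci, fi)
            all_frames.append(ref)
            if nod[fi]:
                nodule_frames.append(ref)
    return all_frames, nodule_frames


def sample_training_batches(mask_stacks: Sequence[MaskStack], batch_size: int,
                            forced_nodule_ratio: float,
                            rng: np.random.Generator, *,
                            policy: str = "forced_nodule",
                            n_batches: int | None = None
                            ) -> Iterator[tuple[list[FrameRef], bool]]:
    """Yield ``(frame_refs, was_forced)`` batches over the given mask stacks.

    ``policy`` selects the imbalance strategy:

    - ``forced_nodule`` (default): with probability ``forced_nodule_ratio``
      a batch is drawn entirely from nodule-bearing frames ("two batches of
      nodule data for every three random batches" corresponds to 2/3);
      otherwise frames are sampled uniformly.
    - ``subsample``: every batch draws ``forced_nodule_ratio`` of its frames
      from nodule-bearing frames and the rest uniformly (subsampling the
      majority class to a fixed nodule rate).
    - ``duplicate``: plain oversampling-by-duplication — nodule frames are
      duplicated once in the sampling pool; batches are uniform over the
      enlarged pool.
    """
    if not 0.0 <= forced_nodule_ratio <= 1.0:
        raise ValueError("forced_nodule_ratio must be in [0, 1]")
    all_frames, nodule_frames = _frame_pool(mask_stacks)
    if not all_frames:
        raise ValueError("no frames to sample from")
    if forced_nodule_ratio > 0 and not nodule_frames and policy != "duplicate":
        raise ValueError(
            "forced_nodule_ratio > 0 but the dataset contains no nodule frames"
        )
    if policy not in ("forced_nodule", "subsample", "duplicate"):
        raise ValueError(f"unknown sampler policy {policy!r}")
    pool = all_frames + nodule_frames if policy == "duplicate" else all_frames

    produced = 0
    while n_batches is None or produced < n_batches:
        if policy == "forced_nodule":
            forced = forced_nodule_ratio > 0 and rng.random() < forced_nodule_ratio
            source = nodule_frames if forced else all_frames
            idx = rng.integers(0, len(source), size=batch_size)
            yield [source[i] for i in idx], forced
        elif policy == "subsample":
            n_forced = int(round(batch_size * forced_nodule_ratio))
            idx_n = rng.integers(0, max(len(nodule_frames), 1), size=n_forced)
            idx_u = rng.integers(0, len(all_frames), size=batch_size - n_forced)
            batch = [nodule_frames[i] for i in idx_n] if nodule_frames else []
            batch += [all_frames[i] for i in idx_u]
            yield batch, n_forced > 0
        else:  # duplicate
            idx = rng.integers(0, len(pool), size=batch_size)
            yield [pool[i] for i in idx], False
        produced += 1


# ---------------------------------------------------------------------------
# persistence


def write_cineclip(path: str | Path, clip: CineClip) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "patient_id": clip.patient_id,
        "side": clip.side,
        "source_shape": list(clip.source_shape) if clip.source_shape else None,
    }
    tifffile.imwrite(path, clip.frames.astype(np.float32),
                     photometric="minisblack",
                     metadata={"cineseg": json.dumps(meta)})


def read_cineclip(path: str | Path) -> CineClip:
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        frames = tf.asarray()
        meta = {}
        raw = (tf.shaped_metadata or [{}])[0].get("cineseg") if tf.shaped_metadata else None
        if raw:
            meta = json.loads(raw)
    if frames.ndim == 2:
        frames = frames[None]
    src = meta.get("source_shape")
    return CineClip(
        frames.astype(np.float32),
        patient_id=meta.get("patient_id", path.stem),
        side=meta.get("side", "unknown"),
        source_shape=tuple(src) if src else None,
    )


def _mask_paths(path: str | Path) -> tuple[Path, Path]:
    base = Path(path)
    stem = base.name
    for suffix in (".thyroid.tiff", ".lesion.tiff", ".tiff", ".tif"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    return (base.parent / f"{stem}.thyroid.tiff", base.parent / f"{stem}.lesion.tiff")


def write_masks(path: str | Path, masks: MaskStack) -> None:
    """Write the two mask layers as parallel multi-page uint8 TIFF stacks."""
    thy_path, les_path = _mask_paths(path)
    thy_path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(thy_path, masks.thyroid.astype(np.uint8),
                     photometric="minisblack")
    tifffile.imwrite(les_path, masks.lesion.astype(np.uint8),
                     photometric="minisblack")


def read_masks(path: str | Path, clip: CineClip | None = None) -> MaskStack:
    thy_path, les_path = _mask_paths(path)
    thy = tifffile.imread(thy_path)
    les = tifffile.imread(les_path)
    if thy.ndim == 2:
        thy = thy[None]
    if les.ndim == 2:
        les = les[None]
    masks = MaskStack(thy, les)
    if clip is not None:
        masks.check_against(clip)
    return masks


def write_manifest(path: str | Path, manifest: DatasetManifest) -> None:
    manifest.validate()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"records": [asdict(r) for r in manifest.records]}
    path.write_text(json.dumps(payload, indent=2))


def read_manifest(path: str | Path) -> DatasetManifest:
    payload = json.loads(Path(path).read_text())
    manifest = DatasetManifest([ManifestRecord(**r) for r in payload["records"]])
    manifest.validate()
    return manifest
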