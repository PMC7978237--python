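"""Synthetic B-mode sweep phantoms with exact ground-truth masks.

The generator emulates the statistical structure of a clinical thyroid
cineclip dataset: a transducer sweep is modelled as uniform-velocity planar
slicing of static 3-D ellipsoids (thyroid band, nodules, cysts), so lesions
grow, shrink and enter/leave the imaging plane across frames and the true
volume of every structure is known in closed form.  Echo texture is
first-order fully-developed speckle: reflectivity multiplied by unit-mean
Gamma noise.  Default prevalence targets match the clinical anchor of
roughly 35% nodule-bearing frames and roughly 2% nodule pixels.

A per-frame *flicker* option renders a lesion at strongly reduced contrast
in the image while leaving the ground-truth mask untouched — emulating
transient obscuration (shadowing, clutter) that only temporal context can
see through.  Masks are always noise-free and unblurred geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .cine_io import (
    CineClip,
    DatasetManifest,
    ManifestRecord,
    MaskStack,
    preprocess_clip,
)

__all__ = [
    "Ellipsoid",
    "LesionSpec",
    "PhantomSpec",
    "generate_cineclip",
    "generate_cohort",
    "compute_prevalence",
    "nodule_phantom_spec",
]

ANECHOIC_LEVEL = 0.03
FLICKER_RESIDUAL_CONTRAST = 0.15


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned 3-D ellipsoid: (row, col, frame) center and semi-axes."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def __post_init__(self):
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("semi-axes must be positive")

    def cross_section(self, t: int) -> tuple[float, float] | None:
        """In-plane semi-axes of the slice at frame ``t`` (None if empty)."""
        cz = self.center[2]
        rz = self.semi_axes[2]
        f = 1.0 - ((t - cz) / rz) ** 2
        if f <= 0:
            return None
        s = np.sqrt(f)
        return self.semi_axes[0] * s, self.semi_axes[1] * s

    @property
    def volume(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c


@dataclass(frozen=True)
class LesionSpec:
    kind: str  # 'cyst' | 'nodule'
    shape: Ellipsoid
    echogenicity: str = "hypo"  # 'hypo' | 'iso' | 'hyper' | 'anechoic'
    margin: str = "smooth"  # 'smooth' | 'ill-defined' | 'lobulated'
    lobulation_amp: float = 0.2  # used when margin == 'lobulated'
    lobulation_order: int = 4

    def __post_init__(self):
        if self.kind not in ("cyst", "nodule"):
            raise ValueError("lesion kind must be 'cyst' or 'nodule'")
        if self.echogenicity not in ("hypo", "iso", "hyper", "anechoic"):
            raise ValueError(f"bad echogenicity {self.echogenicity!r}")
        if self.margin not in ("smooth", "ill-defined", "lobulated"):
            raise ValueError(f"bad margin {self.margin!r}")
        if not 0 <= self.lobulation_amp <= 0.3:
            raise ValueError("lobulation amplitude must be in [0, 0.3]")


@dataclass(frozen=True)
class PhantomSpec:
    """Complete parameterisation of one synthetic sweep phantom."""

    canvas: tuple[int, int] = (64, 64)
    n_frames: int = 16
    thyroid: Ellipsoid = field(
        default_factory=lambda: Ellipsoid((36.0, 32.0, 8.0), (16.0, 27.0, 7.5))
    )
    lesions: tuple[LesionSpec, ...] = ()
    background_level: float = 0.25
    thyroid_level: float = 0.55
    lesion_contrast: float = 0.25
    speckle_shape: float = 4.0
    flicker_prob: float = 0.0
    thyroid_flicker_prob: float = 0.0
    vessel: bool = False
    seed: int = 0

    def __post_init__(self):
        for name in ("background_level", "thyroid_level", "lesion_contrast"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.speckle_shape <= 0:
            raise ValueError("speckle_shape must be positive")
        if not 0.0 <= self.flicker_prob <= 1.0:
            raise ValueError("flicker_prob must be in [0, 1]")
        if not 0.0 <= self.thyroid_flicker_prob <= 1.0:
            raise ValueError("thyroid_flicker_prob must be in [0, 1]")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")


def _ellipse_mask(hw: tuple[int, int], center: tuple[float, float],
                  semi: tuple[float, float], lobulation: tuple[float, int, float] | None
                  ) -> np.ndarray:
    h, w = hw
    yy = (np.arange(h, dtype=np.float64)[:, None] - center[0]) / semi[0]
    xx = (np.arange(w, dtype=np.float64)[None, :] - center[1]) / semi[1]
    rho = np.sqrt(yy**2 + xx**2)
    if lobulation is None:
        return rho <= 1.0
    amp, order, phase = lobulation
    theta = np.arctan2(yy, xx)
    return rho <= 1.0 + amp * np.sin(order * theta + phase)


def _lesion_level(lesion: LesionSpec, spec: PhantomSpec) -> float:
    if lesion.echogenicity == "anechoic":
        return ANECHOIC_LEVEL
    if lesion.echogenicity == "iso":
        return spec.thyroid_level
    if lesion.echogenicity == "hypo":
        return max(spec.thyroid_level - spec.lesion_contrast, 0.0)
    return min(spec.thyroid_level + spec.lesion_contrast, 1.0)


def generate_cineclip(spec: PhantomSpec, patient_id: str = "phantom"
                      ) -> tuple[CineClip, MaskStack, PhantomSpec]:
    """Render a phantom cineclip with its exact ground-truth masks.

    Frame ``t`` contains the plane-``z=t`` cross-sections of all ellipsoids.
    Reflectivity layering: background < thyroid < lesions (drawn in list
    order; nodules drawn after cysts win overlaps).  Ill-defined margins
    blur the lesion's reflectivity edge; lobulated margins perturb the
    boundary with a low-order sinusoid.  Speckle is unit-mean multiplicative
    Gamma noise.  Masks are the exact geometry, noise-free, unaffected by
    flicker.  Deterministic for a fixed spec (the seed lives in the spec).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.canvas
    t_total = spec.n_frames
    frames = np.empty((t_total, h, w), dtype=np.float32)
    thyroid_mask = np.zeros((t_total, h, w), dtype=np.uint8)
    lesion_mask = np.zeros((t_total, h, w), dtype=np.uint8)

    lesions = []
    for lesion in spec.lesions:
        cy, cx, cz = lesion.shape.center
        ry, rx, rz = lesion.shape.semi_axes
        visible = (
            -1 < cz + rz and cz - rz < t_total
            and -1 < cy + ry and cy - ry < h
            and -1 < cx + rx and cx - rx < w
        )
        if not visible:
            warnings.warn(
                f"{lesion.kind} at {lesion.shape.center} lies entirely outside "
                "the canvas/sweep; skipping",
                stacklevel=2,
            )
            continue
        phase = rng.uniform(0, 2 * np.pi)  # one lobulation phase per lesion
        lesions.append((lesion, phase))

    flicker = rng.random((t_total, max(len(lesions), 1))) < spec.flicker_prob
    thy_flicker = rng.random(t_total) < spec.thyroid_flicker_prob

    for t in range(t_total):
        refl = np.full((h, w), spec.background_level, dtype=np.float64)
        thy_sec = spec.thyroid.cross_section(t)
        thy_level = spec.thyroid_level
        if thy_flicker[t]:
            # whole-frame obscuration (shadowing/decoupling): the band is
            # rendered near background contrast; its mask persists
            thy_level = spec.background_level + FLICKER_RESIDUAL_CONTRAST * (
                spec.thyroid_level - spec.background_level
            )
        if thy_sec is not None:
            m = _ellipse_mask((h, w), spec.thyroid.center[:2], thy_sec, None)
            refl[m] = thy_level
            thyroid_mask[t][m] = 1
        if spec.vessel:
            # thin dark tube parallel to the sweep; mimics a blood vessel,
            # deliberately absent from the masks (cyst/vessel confusion)
            vy, vx = int(0.35 * h), int(0.7 * w)
            m = _ellipse_mask((h, w), (vy, vx), (2.0, 2.0), None)
            refl[m] = 0.05
        for li, (lesion, phase) in enumerate(lesions):
            sec = lesion.shape.cross_section(t)
            if sec is None:
                continue
            lob = (
                (lesion.lobulation_amp, lesion.lobulation_order, phase)
                if lesion.margin == "lobulated"
                else None
            )
            m = _ellipse_mask((h, w), lesion.shape.center[:2], sec, lob)
            if not m.any():
                continue
            code = 1 if lesion.kind == "cyst" else 2
            lesion_mask[t][m] = code
            level = _lesion_level(lesion, spec)
            if flicker[t, li]:
                level = thy_level + FLICKER_RESIDUAL_CONTRAST * (level - thy_level)
            if lesion.margin == "ill-defined":
                delta = np.where(m, level - refl, 0.0)
                refl = refl + gaussian_filter(delta, sigma=1.5)
            else:
                refl[m] = level
        noise = rng.gamma(spec.speckle_shape, 1.0 / spec.speckle_shape, size=(h, w))
        frames[t] = np.clip(refl * noise, 0.0, 1.0).astype(np.float32)

    clip = CineClip(frames, patient_id=patient_id)
    masks = MaskStack(thyroid_mask, lesion_mask)
    return clip, masks, spec


def nodule_phantom_spec(canvas: tuple[int, int] = (64, 64), n_frames: int = 16,
                        *, frame_prevalence: float = 0.35,
                        pixel_prevalence: float = 0.02, seed: int = 0,
                        echogenicity: str = "hypo", margin: str = "smooth",
                        flicker_prob: float = 0.0,
                        thyroid_flicker_prob: float = 0.0) -> PhantomSpec:
    """A single-nodule phantom sized to hit given prevalence targets.

    The nodule's frame span is ``frame_prevalence`` of the sweep and its
    in-plane radius solves the ellipsoid-volume equation for the requested
    dataset pixel fraction.
    """
    h, w = canvas
    rz = frame_prevalence * n_frames / 2.0
    r = float(np.sqrt(pixel_prevalence * n_frames * h * w * 3.0 / (4.0 * np.pi * rz)))
    thyroid = Ellipsoid(
        (h * 0.55, w * 0.5, n_frames * 0.5),
        (h * 0.27, w * 0.42, n_frames * 0.47),
    )
    nodule = LesionSpec(
        "nodule",
        Ellipsoid((h * 0.55, w * 0.45, n_frames * 0.5), (r, r, rz)),
        echogenicity=echogenicity,
        margin=margin,
    )
    return PhantomSpec(canvas=canvas, n_frames=n_frames, thyroid=thyroid,
                       lesions=(nodule,), flicker_prob=flicker_prob,
                       thyroid_flicker_prob=thyroid_flicker_prob, seed=seed)


_PATHOLOGIES = (
    ("benign nodule", 0.38),
    ("papillary carcinoma", 0.22),
    ("cystic nodule", 0.2),
    ("multinodular goiter", 0.2),
)
_RARE_PATHOLOGY = "medullary carcinoma"


def generate_cohort(n_patients: int, per_patient_clips: int = 1,
                    prevalence_targets: dict | None = None, seed: int = 0, *,
                    canvas: tuple[int, int] = (64, 64), n_frames: int = 16,
                    flicker_prob: float = 0.0,
                    thyroid_flicker_prob: float | None = None,
                    n_pretrain_extra: int = 2,
                    varied_aspect: bool = True
                    ) -> tuple[list[tuple[CineClip, MaskStack]], DatasetManifest]:
    """Draw a patient cohort of randomized phantoms with a valid manifest.

    Pathology strings are synthesized so stratified splitting is exercised;
    at least one rare pathology (cohort size < 3) appears once ``n_patients
    >= 5``.  A few thyroid-only clips are added with split ``pretrain``
    (the pre-training superset contains clips where only the thyroid was
    annotated).  When ``varied_aspect`` is set, a fraction of patients is
    rendered on a wider canvas and passed through resize-with-padding, so
    the −1 sentinel region appears in the cohort.
    """
    if n_patients < 1:
        raise ValueError("need at least one patient")
    targets = {"frame": 0.35, "pixel": 0.02}
    targets.update(prevalence_targets or {})
    rng = np.random.default_rng(seed)
    h, w = canvas

    patho_names = [p for p, _ in _PATHOLOGIES]
    patho_probs = np.array([q for _, q in _PATHOLOGIES])
    pathologies = [
        patho_names[i]
        for i in rng.choice(len(patho_names), size=n_patients, p=patho_probs)
    ]
    if n_patients >= 5:
        pathologies[int(rng.integers(n_patients))] = _RARE_PATHOLOGY
    counts = {p: pathologies.count(p) for p in set(pathologies)}

    clips: list[tuple[CineClip, MaskStack]] = []
    records: list[ManifestRecord] = []
    for pi in range(n_patients):
        pid = f"P{pi:03d}"
        pathology = pathologies[pi]
        for ci in range(per_patient_clips):
            clip_seed = int(rng.integers(2**31 - 1))
            wide = varied_aspect and rng.random() < 0.3
            render_canvas = (h, int(round(w * 1.3))) if wide else (h, w)
            has_nodule = rng.random() < 0.85
            lesions = []
            echog, margin, malig = "none", "none", "none"
            if has_nodule:
                echog = str(rng.choice(["hypo", "iso", "hyper"], p=[0.5, 0.25, 0.25]))
                margin = str(
                    rng.choice(["smooth", "ill-defined", "lobulated"], p=[0.6, 0.2, 0.2])
                )
                malig = "malignant" if (
                    pathology in ("papillary carcinoma", _RARE_PATHOLOGY)
                ) else "benign"
                span = float(rng.uniform(0.28, 0.42))
                base = nodule_phantom_spec(
                    render_canvas, n_frames,
                    frame_prevalence=span,
                    pixel_prevalence=targets["pixel"] * float(rng.uniform(0.8, 1.25)),
                    echogenicity=echog, margin=margin,
                )
                nod = base.lesions[0]
                jitter = rng.uniform(-0.08, 0.08, size=2)
                nod = replace(
                    nod,
                    shape=Ellipsoid(
                        (
                            nod.shape.center[0] * (1 + jitter[0]),
                            nod.shape.center[1] * (1 + jitter[1]),
                            float(rng.uniform(0.35, 0.65)) * n_frames,
                        ),
                        nod.shape.semi_axes,
                    ),
                )
                lesions.append(nod)
            if rng.random() < 0.4:  # cysts at roughly half the nodule rate
                rcy = float(rng.uniform(3.0, 5.5))
                lesions.append(
                    LesionSpec(
                        "cyst",
                        Ellipsoid(
                            (
                                render_canvas[0] * float(rng.uniform(0.45, 0.65)),
                                render_canvas[1] * float(rng.uniform(0.35, 0.65)),
                                n_frames * float(rng.uniform(0.3, 0.7)),
                            ),
                            (rcy, rcy, float(rng.uniform(0.08, 0.16)) * n_frames),
                        ),
                        echogenicity="anechoic",
                    )
                )
            spec = PhantomSpec(
                canvas=render_canvas, n_frames=n_frames,
                thyroid=Ellipsoid(
                    (
                        render_canvas[0] * float(rng.uniform(0.5, 0.6)),
                        render_canvas[1] * 0.5,
                        n_frames * 0.5,
                    ),
                    (
                        render_canvas[0] * float(rng.uniform(0.24, 0.3)),
                        render_canvas[1] * float(rng.uniform(0.38, 0.45)),
                        n_frames * float(rng.uniform(0.42, 0.49)),
                    ),
                ),
                lesions=tuple(lesions),
                flicker_prob=flicker_prob,
                thyroid_flicker_prob=(
                    flicker_prob * 0.5 if thyroid_flicker_prob is None
                    else thyroid_flicker_prob
                ),
                seed=clip_seed,
            )
            clip, masks, _ = generate_cineclip(spec, patient_id=pid)
            if wide:
                clip, masks = preprocess_clip(clip, masks, target=max(h, w))
            clips.append((clip, masks))
            records.append(
                ManifestRecord(
                    patient_id=pid,
                    clip_path=f"{pid}_{ci}.tiff",
                    mask_path=f"{pid}_{ci}",
                    pathology=pathology,
                    n_pathology_cohort=counts[pathology],
                    echogenicity=echog,
                    margins=margin,
                    malignancy=malig,
                    split="unassigned",
                )
            )

    for ei in range(n_pretrain_extra):
        pid = f"PT{ei:03d}"  # thyroid-only pre-training clips
        spec = PhantomSpec(
            canvas=canvas, n_frames=n_frames, lesions=(),
            thyroid=Ellipsoid(
                (h * 0.55, w * 0.5, n_frames * 0.5),
                (h * 0.26, w * 0.4, n_frames * 0.46),
            ),
            seed=int(rng.integers(2**31 - 1)),
        )
        clip, masks, _ = generate_cineclip(spec, patient_id=pid)
        clips.append((clip, masks))
        records.append(
            ManifestRecord(
                patient_id=pid,
                clip_path=f"{pid}.tiff",
                mask_path=pid,
                pathology="healthy",
                n_pathology_cohort=max(n_pretrain_extra, 3),
                split="pretrain",
            )
        )

    manifest = DatasetManifest(records)
    manifest.validate()
    return clips, manifest


def compute_prevalence(mask_stacks: Sequence[MaskStack]) -> dict:
    """Exact per-class frame and pixel prevalence over a list of mask stacks."""
    if not mask_stacks:
        raise ValueError("compute_prevalence needs at least one mask stack")
    n_frames = 0
    n_pixels = 0
    frame_counts = {"thyroid": 0, "cyst": 0, "nodule": 0}
    pixel_counts = {"thyroid": 0, "cyst": 0, "nodule": 0, "background": 0}
    for masks in mask_stacks:
        t = masks.lesion.shape[0]
        n_frames += t
        n_pixels += masks.lesion.size
        frame_counts["thyroid"] += int(masks.thyroid.any(axis=(1, 2)).sum())
        frame_counts["cyst"] += int((masks.lesion == 1).any(axis=(1, 2)).sum())
        frame_counts["nodule"] += int((masks.lesion == 2).any(axis=(1, 2)).sum())
        pixel_counts["thyroid"] += int(masks.thyroid.sum())
        pixel_counts["cyst"] += int((masks.lesion == 1).sum())
        pixel_counts["nodule"] += int((masks.lesion == 2).sum())
        pixel_counts["background"] += int((masks.lesion == 0).size - np.count_nonzero(masks.lesion))
    return {
        "frame_fraction": {k: v / n_frames for k, v in frame_counts.items()},
        "pixel_fraction": {k: v / n_pixels for k, v in pixel_counts.items()},
    }
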