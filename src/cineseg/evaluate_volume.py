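"""Volume estimation, plane projections and stratified evaluation reports.

A segmented cineclip is a T×H×W label volume: under the constant-uniform-
velocity sweep assumption each frame is a parallel slice, so the volume of
a class is the integral of its per-slice area over the sweep.  The clinical
alternative is the ellipsoid approximation (π/6)·L·W·H from the region's
bounding extents along the three axes.  The percent difference between the
two is signed: negative means the ellipsoid underestimates the integral
volume, which is the expected direction for lobulated or non-ellipsoidal
shapes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .losses_metrics import MetricSet

__all__ = [
    "VolumeReport",
    "integral_volume",
    "ellipsoid_volume",
    "percent_difference",
    "extents",
    "volume_report",
    "project_planes",
    "stratified_report",
]

METRIC_NAMES = ("iou", "mcc", "recall", "precision", "f2")


@dataclass(frozen=True)
class VolumeReport:
    integral_volume: float
    ellipsoid_volume: float
    percent_difference: float | None
    extents: tuple[float, float, float]  # (L, W, H): frame-, x-, y-axis extents


def _check_binary(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 3:
        raise ValueError(f"mask must be T×H×W, got shape {mask.shape}")
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary")
    return mask.astype(bool)


def integral_volume(mask: np.ndarray, spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
                    ) -> float:
    """Σ_t area(mask_t)·dy·dx·dz — slice-area integration over the sweep.

    ``spacing`` is (dz per frame, dy, dx); all must be positive.
    """
    if any(s <= 0 for s in spacing):
        raise ValueError("spacing values must be positive")
    mask = _check_binary(mask)
    dz, dy, dx = spacing
    return float(mask.sum()) * dz * dy * dx


def ellipsoid_volume(length: float, width: float, height: float) -> float:
    """Clinical ellipsoid approximation (π/6)·L·W·H from full extents."""
    if length <= 0 or width <= 0 or height <= 0:
        raise ValueError("extents must be positive")
    return np.pi / 6.0 * length * width * height


def percent_difference(ellipsoid_v: float, integral_v: float) -> float:
    """100·(ellipsoid − integral)/integral; negative = ellipsoid underestimates."""
    if integral_v <= 0:
        raise ValueError("integral volume must be positive")
    return 100.0 * (ellipsoid_v - integral_v) / integral_v


def extents(mask: np.ndarray, spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
            ) -> tuple[float, float, float]:
    """Caliper extents (L, W, H) along the three axes through the centroid.

    Mimics the clinical measurement: each extent is the span of the region
    along the axis line passing through the region's center of mass (falling
    back to the bounding span when that line misses the region).  Spans are
    distances between the outermost crossed voxel centers, which makes the
    measurement exact in the digitized-ellipsoid limit.
    """
    mask = _check_binary(mask)
    if not mask.any():
        return (0.0, 0.0, 0.0)
    dz, dy, dx = spacing
    ct, cy, cx = (int(round(c)) for c in
                  np.array(np.nonzero(mask)).mean(axis=1))

    def span(values: np.ndarray, fallback: np.ndarray) -> float:
        hits = np.flatnonzero(values)
        if hits.size == 0:
            hits = np.flatnonzero(fallback)
        return float(max(hits[-1] - hits[0], 1))

    t_line = span(mask[:, cy, cx], mask.any(axis=(1, 2)))
    y_line = span(mask[ct, :, cx], mask.any(axis=(0, 2)))
    x_line = span(mask[ct, cy, :], mask.any(axis=(0, 1)))
    return (t_line * dz, x_line * dx, y_line * dy)


def volume_report(mask: np.ndarray, spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
                  ) -> VolumeReport:
    """Integral vs ellipsoid volume of one class region."""
    iv = integral_volume(mask, spacing)
    ext = extents(mask, spacing)
    ev = ellipsoid_volume(*ext) if all(e > 0 for e in ext) else 0.0
    pd_ = percent_difference(ev, iv) if iv > 0 else None
    return VolumeReport(iv, ev, pd_, ext)


def project_planes(mask: np.ndarray) -> dict[str, np.ndarray]:
    """Sum-projections of a T×H×W mask along each axis (three planes).

    The sum over any projection equals the voxel count of the class.
    """
    mask = np.asarray(mask)
    if mask.ndim != 3:
        raise ValueError(f"mask must be T×H×W, got {mask.shape}")
    m = mask.astype(np.int64)
    return {
        "axial": m.sum(axis=0),  # H×W, summing over frames
        "coronal": m.sum(axis=1),  # T×W
        "sagittal": m.sum(axis=2),  # T×H
    }


def stratified_report(per_clip_metrics: Sequence[Mapping[str, MetricSet]],
                      strata_labels: Sequence[str],
                      classes: Sequence[str] = ("cyst", "nodule", "thyroid"),
                      empty_marker: str = "-") -> pd.DataFrame:
    """Per-stratum mean and standard deviation tables of per-clip metrics.

    ``per_clip_metrics[i]`` maps class name → MetricSet for clip ``i``;
    ``strata_labels[i]`` is the clip's stratum (e.g. its echogenicity).
    Strata or classes with no clips emit the ``empty_marker``.  Standard
    deviations are population (ddof 0) over clips within the stratum.
    """
    if len(per_clip_metrics) != len(strata_labels):
        raise ValueError("metrics and strata labels are misaligned")
    strata = sorted(set(strata_labels))
    rows = []
    for stratum in strata:
        sel = [m for m, s in zip(per_clip_metrics, strata_labels) if s == stratum]
        for cls in classes:
            values = {
                k: [m[cls].as_dict()[k] for m in sel if cls in m] for k in METRIC_NAMES
            }
            has = bool(values["iou"])
            rows.append(
                {"feature": f"{cls.capitalize()} Mean", "stratum": stratum,
                 **{k: (float(np.mean(v)) if has else empty_marker)
                    for k, v in values.items()}}
            )
            rows.append(
                {"feature": f"{cls.capitalize()} Std.", "stratum": stratum,
                 **{k: (float(np.std(v)) if has else empty_marker)
                    for k, v in values.items()}}
            )
    return pd.DataFrame(rows, columns=["feature", *METRIC_NAMES, "stratum"])
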