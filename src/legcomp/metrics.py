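"""Per-slice body-composition metrics and decade-level aggregation.

Metrics are computed bilaterally (the sum of both legs) per axial slice:
SAT volume (mL), muscle volume (mL) and the SAT-to-muscle volume ratio.
Slices are then partitioned into ten contiguous "decades" each holding 10%
of the analyzed slices -- a height-normalized axis along the leg with decade
1 at the ankle end and decade 10 at the superior thigh -- and per-slice
metrics are averaged within each decade.  Limb circumference is measured on
the subject-left leg as the physical length of the leg mask's outer contour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import find_contours, label, regionprops

from .segmentation import SliceMasks

logger = logging.getLogger(__name__)

__all__ = [
    "SliceMetrics",
    "DecadeSummary",
    "slice_metrics",
    "decade_partition",
    "decade_summaries",
    "limb_circumference",
    "representative_slices",
]


@dataclass
class SliceMetrics:
    """Bilateral composition metrics for one axial slice."""

    slice_index: int
    sat_volume_ml: float
    muscle_volume_ml: float
    sat_muscle_ratio: float  # NaN when undefined (zero muscle volume)
    ratio_defined: bool
    circumference_cm: float | None = None


@dataclass
class DecadeSummary:
    """Unweighted per-slice means over one decade of the leg."""

    decade: int                 # 1 (ankle end) ... 10 (superior thigh)
    slice_start: int
    slice_stop: int             # exclusive
    n_slices: int
    mean_sat_volume_ml: float
    mean_muscle_volume_ml: float
    mean_sat_muscle_ratio: float  # NaN if no slice in the decade has a defined ratio
    n_ratio_undefined: int


def slice_metrics(masks: SliceMasks, voxel_spacing: tuple[float, float, float],
                  slice_index: int = 0) -> SliceMetrics:
    """SAT/muscle volumes (mL) and their ratio for one segmented slice.

    Volume is the voxel count times the voxel volume; with both legs in the
    slice masks the counts are inherently bilateral.  A slice with zero
    muscle volume gets an undefined (NaN) ratio rather than zero or
    infinity.
    """
    if any(s <= 0 for s in voxel_spacing):
        raise ValueError("voxel spacing must be positive")
    voxel_ml = voxel_spacing[0] * voxel_spacing[1] * voxel_spacing[2] / 1000.0
    sat_ml = float(masks.sat.sum()) * voxel_ml
    muscle_ml = float(masks.muscle_final.sum()) * voxel_ml
    defined = muscle_ml > 0
    ratio = sat_ml / muscle_ml if defined else float("nan")
    if not defined:
        logger.info("slice %d: zero muscle volume, SAT-to-muscle ratio undefined", slice_index)
    return SliceMetrics(slice_index, sat_ml, muscle_ml, ratio, defined)


def decade_partition(n_slices: int) -> list[range]:
    """Ten contiguous slice ranges with boundaries at ``floor(d*n/10)``.

    The ranges are disjoint, cover every slice, and differ in size by at
    most one; decade 1 is the most inferior (ankle) end.
    """
    if n_slices < 10:
        raise ValueError(f"need at least 10 slices to form decades, got {n_slices}")
    bounds = [(d * n_slices) // 10 for d in range(11)]
    return [range(bounds[d], bounds[d + 1]) for d in range(10)]


def decade_summaries(metrics: list[SliceMetrics]) -> list[DecadeSummary]:
    """Mean per-slice metrics over each decade.

    Slices with an undefined SAT-to-muscle ratio are excluded from (not
    zero-filled into) the ratio mean and counted per decade.
    """
    ranges = decade_partition(len(metrics))
    out = []
    for d, rng in enumerate(ranges, start=1):
        chunk = [metrics[i] for i in rng]
        sat = float(np.mean([m.sat_volume_ml for m in chunk]))
        mus = float(np.mean([m.muscle_volume_ml for m in chunk]))
        ratios = [m.sat_muscle_ratio for m in chunk if m.ratio_defined]
        n_undef = len(chunk) - len(ratios)
        if n_undef:
            logger.info("decade %d: %d slice(s) with undefined ratio excluded", d, n_undef)
        ratio = float(np.mean(ratios)) if ratios else float("nan")
        out.append(DecadeSummary(d, rng.start, rng.stop, len(chunk), sat, mus, ratio, n_undef))
    return out


def representative_slices(n_slices: int) -> dict[str, int]:
    """Middle slice of decade 3 ("calf") and decade 7 ("thigh")."""
    ranges = decade_partition(n_slices)
    return {
        "calf": ranges[2][len(ranges[2]) // 2],
        "thigh": ranges[6][len(ranges[6]) // 2],
    }


def _outer_contour_length_mm(component: np.ndarray,
                             voxel_spacing: tuple[float, float, float]) -> float:
    # Smooth the binary mask before marching squares: the raw staircase
    # contour overestimates a smooth perimeter by several percent.
    smoothed = ndimage.gaussian_filter(np.pad(component.astype(float), 3), sigma=1.0)
    contours = find_contours(smoothed, 0.5)
    if not contours:
        raise ValueError("component has no iso-contour")
    outer = max(contours, key=lambda c: c.shape[0])
    d = np.diff(outer, axis=0)
    return float(np.sqrt((d[:, 0] * voxel_spacing[0]) ** 2
                         + (d[:, 1] * voxel_spacing[1]) ** 2).sum())


def limb_circumference(leg_mask: np.ndarray,
                       voxel_spacing: tuple[float, float, float],
                       side: str = "left") -> float:
    """Perimeter (cm) of one leg's outer contour in physical coordinates.

    ``side`` is the subject's side; subject-left appears on image-right
    under the radiological convention, so the component whose centroid lies
    right of the image midline is selected.  Anisotropic in-plane spacing is
    respected by scaling contour segments per axis.
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    if not leg_mask.any():
        raise ValueError("empty leg mask")
    labeled, n = label(leg_mask, return_num=True, connectivity=2)
    midline = leg_mask.shape[1] / 2.0
    if n == 1:
        centroid_col = regionprops(labeled)[0].centroid[1]
        if abs(centroid_col - midline) < 0.1 * leg_mask.shape[1]:
            raise ValueError("legs appear merged into a single component at "
                             "the midline; cannot resolve sides")
    props = regionprops(labeled)
    wanted = [p for p in props
              if (p.centroid[1] > midline) == (side == "left")]
    if not wanted:
        raise ValueError(f"no leg component found on the subject-{side} side")
    comp = labeled == max(wanted, key=lambda p: p.area).label
    return _outer_contour_length_mm(comp, voxel_spacing) / 10.0
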