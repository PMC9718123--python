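"""Hoffa-synovitis (HS) quantification on sagittal stacks.

Four polygonal ROIs are drawn over Hoffa's fat pad on the sagittal slices
i-3, i-1, i+1, i+3 around the patellar-center slice i.  The hyperintensity
threshold is derived from a homogeneous reference ROI (sampled within the
femur) as ``mean + k * sd``; X_Hoff is the total volume of ROI voxels whose
intensity strictly exceeds that threshold.

Tie convention: exceedance is strict (>) here, unlike the inclusive (>=)
convention of the effusion module — an ROI sitting exactly at the threshold
contributes zero volume.

The k multiplier, the slice-offset set and an ROI-area floor are exposed to a
small calibration harness (:func:`calibrate_hoffa`) that scans a parameter
grid for the Spearman-correlation maximizer against ordinal grades, mirroring
how such scoring software is trained against a semi-quantitative standard.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .image_core import ImageVolume, PolygonROI

__all__ = [
    "HoffaSliceScheme",
    "ReferenceSample",
    "HoffaAssessment",
    "select_hoffa_slices",
    "sample_reference",
    "compute_x_hoff",
    "calibrate_hoffa",
    "HoffaCase",
]

MIN_REFERENCE_VOXELS = 25  # stability floor for the reference mean/sd


@dataclass(frozen=True)
class HoffaSliceScheme:
    """Patellar-center slice index plus the assessed slice offsets."""

    center_slice_i: int
    offsets: tuple[int, ...] = (-3, -1, 1, 3)

    def __post_init__(self) -> None:
        offs = tuple(int(o) for o in self.offsets)
        if len(set(offs)) != len(offs):
            raise ValueError(f"offsets must be distinct, got {offs}")
        object.__setattr__(self, "offsets", offs)


@dataclass(frozen=True)
class ReferenceSample:
    """Reference-region intensity statistics and the derived threshold."""

    roi: PolygonROI
    mean: float
    sd: float
    k: float

    @property
    def threshold(self) -> float:
        return self.mean + self.k * self.sd


@dataclass(frozen=True)
class HoffaAssessment:
    """Result of one knee's Hoffa-synovitis measurement."""

    scheme: HoffaSliceScheme
    rois: tuple[PolygonROI, ...]
    threshold: float
    per_roi_volume_mm3: tuple[float, ...]
    x_hoff_mm3: float
    per_roi_supra_voxels: tuple[int, ...] = ()


def select_hoffa_slices(scheme: HoffaSliceScheme, volume: ImageVolume) -> tuple[int, ...]:
    """Slice indices i + offset, ascending; errors if any falls outside the stack."""
    indices = sorted(scheme.center_slice_i + o for o in scheme.offsets)
    bad = [i for i in indices if not 0 <= i < volume.n_slices]
    if bad:
        raise ValueError(
            f"scheme slices {bad} out of bounds for volume with {volume.n_slices} slices"
        )
    return tuple(indices)


def sample_reference(volume: ImageVolume, roi: PolygonROI, k: float = 2.0) -> ReferenceSample:
    """Sample the reference ROI: mean, unbiased sd, and threshold mean + k*sd."""
    if roi.slice_index >= volume.n_slices:
        raise ValueError(f"reference ROI slice {roi.slice_index} out of bounds")
    plane = volume.get_slice(roi.slice_index)
    sel = roi.rasterize_slice(plane.shape)
    n = int(sel.sum())
    if n < MIN_REFERENCE_VOXELS:
        raise ValueError(
            f"reference ROI rasterizes to {n} voxels; need >= {MIN_REFERENCE_VOXELS} "
            "for a stable threshold"
        )
    values = plane[sel].astype(np.float64)
    return ReferenceSample(
        roi=roi, mean=float(values.mean()), sd=float(values.std(ddof=1)), k=float(k)
    )


def compute_x_hoff(
    volume: ImageVolume,
    scheme: HoffaSliceScheme,
    rois: Sequence[PolygonROI],
    reference: ReferenceSample,
    min_roi_area_mm2: float = 0.0,
) -> HoffaAssessment:
    """X_Hoff: volume of ROI voxels strictly exceeding the reference threshold.

    Each ROI must lie on one of the scheme's slices.  ROIs whose rasterized
    area falls below ``min_roi_area_mm2`` contribute zero volume (area floor
    used by the calibration harness); exceedance is strict (>).
    """
    scheme_slices = set(select_hoffa_slices(scheme, volume))
    got = {roi.slice_index for roi in rois}
    stray = got - scheme_slices
    if stray:
        raise ValueError(
            f"ROI slices {sorted(stray)} are not scheme slices {sorted(scheme_slices)}"
        )
    threshold = reference.threshold
    vv = volume.voxel_volume_mm3
    area = volume.in_plane_area_mm2
    per_counts: list[int] = []
    per_vol: list[float] = []
    for roi in rois:
        plane = volume.get_slice(roi.slice_index)
        sel = roi.rasterize_slice(plane.shape)
        if sel.sum() * area < min_roi_area_mm2:
            per_counts.append(0)
            per_vol.append(0.0)
            continue
        n_supra = int(np.count_nonzero(plane[sel] > threshold))
        per_counts.append(n_supra)
        per_vol.append(n_supra * vv)
    return HoffaAssessment(
        scheme=scheme,
        rois=tuple(rois),
        threshold=float(threshold),
        per_roi_volume_mm3=tuple(per_vol),
        x_hoff_mm3=float(sum(per_vol)),
        per_roi_supra_voxels=tuple(per_counts),
    )


# ---------------------------------------------------------------------------
# Calibration harness


@dataclass(frozen=True)
class HoffaCase:
    """One graded knee for calibration: volume, geometry and ordinal grade.

    ``rois_by_offset`` must supply a fat-pad ROI for every offset any grid
    point may request.
    """

    volume: ImageVolume
    center_slice_i: int
    rois_by_offset: Mapping[int, PolygonROI]
    reference_roi: PolygonROI
    grade: int


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    from scipy import stats

    if np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan
    return float(stats.spearmanr(x, y).statistic)


def calibrate_hoffa(
    cases: Sequence[HoffaCase],
    k_values: Iterable[float],
    offset_sets: Iterable[tuple[int, ...]] = ((-3, -1, 1, 3),),
    min_roi_area_mm2_values: Iterable[float] = (0.0,),
) -> tuple[dict, pd.DataFrame]:
    """Grid-search (k, offsets, area floor) for maximum Spearman r vs grade.

    Every grid point is evaluated exactly once; grid points where X_Hoff is
    constant across the cohort have undefined correlation and are recorded as
    NaN and skipped for the argmax.  Ties break toward smaller k, then
    smaller summed |offsets|.

    Returns ``(best_params, trace)`` where trace is a DataFrame with one row
    per grid point (k, offsets, min_roi_area_mm2, spearman_r).
    """
    cases = list(cases)
    if len(cases) < 10:
        raise ValueError(f"calibration needs >= 10 graded knees, got {len(cases)}")
    k_values = sorted(float(k) for k in k_values)
    offset_sets = [tuple(int(o) for o in s) for s in offset_sets]
    min_areas = sorted(float(a) for a in min_roi_area_mm2_values)
    if not k_values or not offset_sets or not min_areas:
        raise ValueError("parameter grid must be non-empty")

    grades = np.array([c.grade for c in cases], dtype=float)
    rows = []
    for offsets in offset_sets:
        schemes = [HoffaSliceScheme(c.center_slice_i, offsets) for c in cases]
        rois = []
        for c in cases:
            missing = [o for o in offsets if o not in c.rois_by_offset]
            if missing:
                raise ValueError(f"case lacks ROIs for offsets {missing}")
            rois.append([c.rois_by_offset[o] for o in offsets])
        for k in k_values:
            refs = [sample_reference(c.volume, c.reference_roi, k) for c in cases]
            for min_area in min_areas:
                x = np.array(
                    [
                        compute_x_hoff(c.volume, sch, rs, ref, min_area).x_hoff_mm3
                        for c, sch, rs, ref in zip(cases, schemes, rois, refs)
                    ]
                )
                rows.append(
                    {
                        "k": k,
                        "offsets": offsets,
                        "min_roi_area_mm2": min_area,
                        "spearman_r": _spearman(x, grades),
                    }
                )
    trace = pd.DataFrame(rows)
    valid = trace.dropna(subset=["spearman_r"])
    if valid.empty:
        raise ValueError("correlation undefined at every grid point")
    # argmax with ties toward smaller k, then smaller summed |offsets|
    key = valid.assign(
        _abs_off=[sum(abs(o) for o in offs) for offs in valid["offsets"]]
    ).sort_values(["spearman_r", "k", "_abs_off"], ascending=[False, True, True])
    best = key.iloc[0]
    best_params = {
        "k": float(best["k"]),
        "offsets": tuple(best["offsets"]),
        "min_roi_area_mm2": float(best["min_roi_area_mm2"]),
        "spearman_r": float(best["spearman_r"]),
    }
    return best_params, trace
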