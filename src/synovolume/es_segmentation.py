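"""Effusion-synovitis (ES) quantification on axial stacks.

The workflow mirrors a reader session with a thresholding GUI, made scriptable
and replayable:

1. resolve an intensity threshold over the patella slice range
   (:func:`resolve_threshold`): an absolute value, an empirical quantile, or
   an Otsu split restricted to the range;
2. label every supra-threshold connected component slice by slice
   (:func:`auto_label_slices`), optionally flagging components below an area
   floor as likely irrelevant signal;
3. replay reader edits as an explicit rejection list (:func:`apply_edits`);
4. sum accepted areas across slices into the total effusion volume V_Eff and
   the per-slice normalized volume V_Norm (:func:`compute_v_eff`).

Supra-threshold is *inclusive* (intensity >= threshold) throughout this
module.  Region growing is 2-D within each slice, because the volume is
defined as the per-slice effusion area summed across the assessed slices;
in-plane connectivity is 8 by default with 4 available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import ndimage

from .image_core import BinaryMask, ImageVolume, SliceRange

__all__ = [
    "ThresholdSpec",
    "Region",
    "CandidateRegions",
    "SegmentationResult",
    "DegenerateInputError",
    "resolve_threshold",
    "region_grow_slice",
    "auto_label_slices",
    "apply_edits",
    "compute_v_eff",
    "segment_effusion",
]

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


class DegenerateInputError(ValueError):
    """Raised when an automatic threshold cannot be computed."""


@dataclass(frozen=True)
class ThresholdSpec:
    """How to resolve the segmentation threshold over a slice range.

    mode
        ``"absolute"``: use ``value`` as the intensity threshold.
        ``"quantile"``: ``value`` in (0, 1); the empirical quantile of the
        intensities within ``applies_to`` (linear interpolation).
        ``"otsu_within_range"``: ignore ``value``; maximize between-class
        variance over a 256-bin histogram of the range.
    """

    mode: Literal["absolute", "quantile", "otsu_within_range"]
    value: float | None = None
    applies_to: SliceRange | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("absolute", "quantile", "otsu_within_range"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if self.mode == "absolute":
            if self.value is None or not np.isfinite(self.value):
                raise ValueError("absolute mode requires a finite value")
        elif self.mode == "quantile":
            if self.value is None or not 0 < self.value < 1:
                raise ValueError("quantile fraction must be strictly in (0, 1)")


def _range_intensities(volume: ImageVolume, slice_range: SliceRange) -> np.ndarray:
    slice_range.validate_for(volume)
    taken = np.take(volume.data, list(slice_range.indices), axis=volume.slice_axis)
    return np.asarray(taken, dtype=np.float64).ravel()


def otsu_threshold(values: np.ndarray, n_bins: int = 256) -> float:
    """Between-class-variance-maximizing split of a histogram.

    The histogram has ``n_bins`` equal bins over the observed min-max.
    Candidate thresholds are the interior bin edges; the returned threshold
    separates intensities < t from intensities >= t.  Ties are broken toward
    the lower split value.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        raise DegenerateInputError(
            "constant-intensity region: Otsu threshold undefined; use absolute mode"
        )
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    w = counts / counts.sum()
    mids = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(w)[:-1]          # class weight below each interior edge
    w1 = 1.0 - w0
    cmean = np.cumsum(w * mids)[:-1]
    total = float(np.sum(w * mids))
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cmean / w0
        mu1 = (total - cmean) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between = np.where(np.isfinite(between), between, -np.inf)
    # ties break toward the lower split; a relative tolerance makes the rule
    # robust to float noise on the exact plateaus that empty bins create
    peak = float(between.max())
    best = int(np.argmax(between >= peak - 1e-9 * abs(peak)))
    return float(edges[1:-1][best])


def resolve_threshold(volume: ImageVolume, spec: ThresholdSpec) -> float:
    """Resolve a :class:`ThresholdSpec` to an absolute intensity."""
    if spec.mode == "absolute":
        return float(spec.value)
    if spec.applies_to is None:
        raise ValueError(f"{spec.mode} mode requires an applies_to slice range")
    values = _range_intensities(volume, spec.applies_to)
    if spec.mode == "quantile":
        return float(np.quantile(values, spec.value, method="linear"))
    return otsu_threshold(values)


# ---------------------------------------------------------------------------
# Region growing and candidate bookkeeping


def region_grow_slice(
    slice_image: np.ndarray,
    threshold: float,
    seeds: Iterable[tuple[int, int]],
    connectivity: int = 8,
) -> list[np.ndarray]:
    """Grow regions from seeds over supra-threshold (>= threshold) voxels.

    Returns one boolean mask per distinct connected component reached by a
    seed, in order of first reaching seed.  Sub-threshold seeds contribute no
    component; duplicate seeds within a component yield that component once.
    The result is independent of seed order and of which in-component voxel
    seeds it.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    img = np.asarray(slice_image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("slice_image must be 2-D")
    supra = img >= threshold
    labels, _ = ndimage.label(supra, structure=_STRUCTURES[connectivity])
    out: list[np.ndarray] = []
    seen: set[int] = set()
    for r, c in seeds:
        if not (0 <= r < img.shape[0] and 0 <= c < img.shape[1]):
            raise ValueError(f"seed ({r}, {c}) out of bounds for shape {img.shape}")
        lab = int(labels[r, c])
        if lab == 0 or lab in seen:
            continue
        seen.add(lab)
        out.append(labels == lab)
    return out


@dataclass
class Region:
    """One connected supra-threshold component on one slice."""

    slice_index: int
    label: int
    n_voxels: int
    area_mm2: float
    seed: tuple[int, int]
    flagged_sub_minimal: bool = False
    accepted: bool = True


@dataclass
class CandidateRegions:
    """Per-slice labeling of all supra-threshold components in a slice range."""

    volume: ImageVolume
    slice_range: SliceRange
    threshold: float
    connectivity: int
    labels_by_slice: dict[int, np.ndarray]
    regions: list[Region]

    def region_map(self) -> dict[tuple[int, int], Region]:
        return {(reg.slice_index, reg.label): reg for reg in self.regions}

    def accepted_mask(self) -> BinaryMask:
        voxels = np.zeros(self.volume.shape, dtype=bool)
        for reg in self.regions:
            if not reg.accepted:
                continue
            plane = self.labels_by_slice[reg.slice_index] == reg.label
            idx: list[slice | int] = [slice(None)] * 3
            idx[self.volume.slice_axis] = reg.slice_index
            voxels[tuple(idx)] |= plane
        return BinaryMask(voxels=voxels, slice_axis=self.volume.slice_axis)


def auto_label_slices(
    volume: ImageVolume,
    slice_range: SliceRange,
    threshold: float,
    connectivity: int = 8,
    min_area_mm2: float = 0.0,
) -> CandidateRegions:
    """Label every supra-threshold component on every slice of the range.

    Components with area below ``min_area_mm2`` are *flagged* as sub-minimal
    (likely irrelevant signal) but not deleted; all candidates start accepted.
    """
    slice_range.validate_for(volume)
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    area_per_voxel = volume.in_plane_area_mm2
    labels_by_slice: dict[int, np.ndarray] = {}
    regions: list[Region] = []
    for s in slice_range.indices:
        plane = volume.get_slice(s)
        labels, n = ndimage.label(plane >= threshold, structure=_STRUCTURES[connectivity])
        labels_by_slice[s] = labels
        for lab in range(1, n + 1):
            rr, cc = np.nonzero(labels == lab)
            n_vox = rr.size
            area = n_vox * area_per_voxel
            regions.append(
                Region(
                    slice_index=s,
                    label=lab,
                    n_voxels=int(n_vox),
                    area_mm2=float(area),
                    seed=(int(rr[0]), int(cc[0])),
                    flagged_sub_minimal=bool(area < min_area_mm2),
                )
            )
    return CandidateRegions(
        volume=volume,
        slice_range=slice_range,
        threshold=float(threshold),
        connectivity=connectivity,
        labels_by_slice=labels_by_slice,
        regions=regions,
    )


def apply_edits(
    candidates: CandidateRegions,
    rejections: Sequence[tuple[int, int]] = (),
    reject_flagged: bool = False,
) -> CandidateRegions:
    """Replay reader edits: mark the listed (slice, label) regions rejected.

    Idempotent; with ``reject_flagged`` every sub-minimal-flagged region is
    rejected as well.  Unknown pairs raise with the offending pair named.
    """
    rmap = candidates.region_map()
    for pair in rejections:
        key = (int(pair[0]), int(pair[1]))
        if key not in rmap:
            raise ValueError(f"no candidate region (slice={key[0]}, label={key[1]})")
        rmap[key].accepted = False
    if reject_flagged:
        for reg in candidates.regions:
            if reg.flagged_sub_minimal:
                reg.accepted = False
    return candidates


# ---------------------------------------------------------------------------
# Volume accounting


@dataclass
class SegmentationResult:
    """Accepted-mask segmentation with derived ES volumes.

    v_eff_mm3 is the accepted effusion area summed over the assessed slices
    times the slice thickness; v_norm_mm3_per_slice divides it by the number
    of slices in the patella range.
    """

    mask: BinaryMask
    slice_range: SliceRange
    threshold_used: float
    per_slice_area_mm2: np.ndarray  # one entry per slice in the range
    v_eff_mm3: float
    v_norm_mm3_per_slice: float
    regions: list[Region] = field(default_factory=list)
    connectivity: int = 8


def compute_v_eff(
    mask: BinaryMask,
    spacing: Sequence[float],
    slice_range: SliceRange,
    slice_axis: int | None = None,
) -> tuple[float, float, np.ndarray]:
    """V_Eff, V_Norm and per-slice areas from an accepted mask.

    per-slice area = accepted voxel count x dx*dy; V_Eff = sum(area) x dz;
    V_Norm = V_Eff / slice count of the range.  The mask must be empty
    outside the range.
    """
    spacing = tuple(float(s) for s in spacing)
    axis = mask.slice_axis if slice_axis is None else slice_axis
    counts = mask.voxels.sum(axis=tuple(a for a in range(3) if a != axis))
    if slice_range.last >= counts.size:
        raise ValueError("slice range exceeds mask extent")
    outside = counts.sum() - counts[slice_range.first : slice_range.last + 1].sum()
    if outside:
        raise ValueError(f"mask has {int(outside)} accepted voxels outside the slice range")
    in_plane = np.prod([s for ax, s in enumerate(spacing) if ax != axis])
    dz = spacing[axis]
    per_slice_area = counts[slice_range.first : slice_range.last + 1] * float(in_plane)
    v_eff = float(per_slice_area.sum() * dz)
    v_norm = v_eff / slice_range.count
    return v_eff, v_norm, per_slice_area.astype(np.float64)


def segment_effusion(
    volume: ImageVolume,
    slice_range: SliceRange,
    threshold: ThresholdSpec | float,
    connectivity: int = 8,
    min_area_mm2: float = 0.0,
    rejections: Sequence[tuple[int, int]] = (),
    reject_flagged: bool = False,
) -> SegmentationResult:
    """End-to-end ES quantification: threshold, label, edit, measure."""
    if isinstance(threshold, ThresholdSpec):
        spec = threshold
        if spec.applies_to is None and spec.mode != "absolute":
            spec = ThresholdSpec(mode=spec.mode, value=spec.value, applies_to=slice_range)
        thr = resolve_threshold(volume, spec)
    else:
        thr = float(threshold)
    candidates = auto_label_slices(volume, slice_range, thr, connectivity, min_area_mm2)
    apply_edits(candidates, rejections, reject_flagged=reject_flagged)
    mask = candidates.accepted_mask()
    v_eff, v_norm, per_slice = compute_v_eff(mask, volume.spacing, slice_range)
    return SegmentationResult(
        mask=mask,
        slice_range=slice_range,
        threshold_used=thr,
        per_slice_area_mm2=per_slice,
        v_eff_mm3=v_eff,
        v_norm_mm3_per_slice=v_norm,
        regions=candidates.regions,
        connectivity=connectivity,
    )
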