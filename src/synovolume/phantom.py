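"""Synthetic knee phantoms with exactly known ground truth.

The phantoms are deliberately minimal geometric scenes, not anatomical
simulations: an axial stack carries a hyperintense ellipsoidal fluid pocket
(the suprapatellar effusion analog) over a uniform background, and a sagittal
stack carries a homogeneous fat block with a reference region plus four
fat-pad ROIs seeded with a known fraction of hyperintense voxels (the
Hoffa-synovitis analog).

Ground truth is defined on the *noiseless* image by voxel-center membership —
the same convention as ROI rasterization — so that recovery errors measure
algorithmic behavior rather than convention mismatch.  Noise is additive
Gaussian by default (adequate at the SNR of fluid-sensitive sequences and
simple to reason about); a Rician option is available for realism.
Generation is bit-reproducible given (spec, seed).

:func:`simulate_cohort` extends the phantoms into a desk-scale case-control
study: ordinal grades drive true volumes through a monotone grade-to-volume
map, progression-group membership applies a weak multiplicative effect, and
a two-reader error model produces the repeated measurements that feed the
validation battery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .image_core import ImageVolume, PolygonROI, SliceRange

__all__ = [
    "AxialPhantomSpec",
    "SagittalPhantomSpec",
    "GroundTruth",
    "CohortModel",
    "ReaderModel",
    "make_axial_phantom",
    "make_sagittal_phantom",
    "simulate_cohort",
    "separable_axial_spec",
    "default_sagittal_spec",
]


@dataclass(frozen=True)
class GroundTruth:
    """Exact noiseless ground truth for a phantom."""

    true_fluid_voxels: int
    true_volume_mm3: float
    per_slice_true_areas_mm2: tuple[float, ...] = ()
    per_roi_supra_counts: tuple[int, ...] = ()


@dataclass(frozen=True)
class AxialPhantomSpec:
    """Axial effusion phantom: ellipsoidal fluid pocket on uniform background.

    Spacing defaults to 0.5 x 0.5 mm in-plane with 1.5 mm slices — plausible
    MR values chosen for the phantom, not taken from any acquisition protocol.
    Separable presets keep fluid-background contrast >= 4 x noise_sd so the
    threshold is recoverable.
    """

    shape: tuple[int, int, int] = (64, 64, 24)
    spacing: tuple[float, float, float] = (0.5, 0.5, 1.5)
    background_mean: float = 40.0
    fluid_mean: float = 200.0
    noise_sd: float = 0.0
    ellipsoid_center_mm: tuple[float, float, float] = (16.0, 16.0, 17.25)
    ellipsoid_semi_axes_mm: tuple[float, float, float] = (10.0, 8.0, 6.0)
    patella_range: SliceRange = field(default_factory=lambda: SliceRange(7, 16))
    noise_model: str = "gaussian"  # or "rician"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fluid_mean <= self.background_mean:
            raise ValueError("fluid_mean must exceed background_mean")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    @property
    def contrast(self) -> float:
        return self.fluid_mean - self.background_mean

    @property
    def is_separable(self) -> bool:
        return self.noise_sd == 0 or self.contrast >= 4 * self.noise_sd


def _voxel_coords(n: int, d: float) -> np.ndarray:
    return np.arange(n, dtype=np.float64) * d


def _ellipsoid_membership(spec: AxialPhantomSpec) -> np.ndarray:
    cx, cy, cz = spec.ellipsoid_center_mm
    a, b, c = spec.ellipsoid_semi_axes_mm
    nx, ny, nz = spec.shape
    dx, dy, dz = spec.spacing
    # the ellipsoid must lie fully inside the grid of voxel centers
    for center, semi, n, d in ((cx, a, nx, dx), (cy, b, ny, dy), (cz, c, nz, dz)):
        if center - semi < 0 or center + semi > (n - 1) * d:
            raise ValueError("ellipsoid is clipped by the grid")
    x = (_voxel_coords(nx, dx) - cx) / a
    y = (_voxel_coords(ny, dy) - cy) / b
    z = (_voxel_coords(nz, dz) - cz) / c
    return (
        x[:, None, None] ** 2 + y[None, :, None] ** 2 + z[None, None, :] ** 2
    ) <= 1.0


def _add_noise(noiseless: np.ndarray, spec, rng: np.random.Generator) -> np.ndarray:
    if spec.noise_sd == 0:
        return noiseless.copy()
    if spec.noise_model == "rician":
        re = noiseless + rng.normal(0.0, spec.noise_sd, noiseless.shape)
        im = rng.normal(0.0, spec.noise_sd, noiseless.shape)
        return np.hypot(re, im)
    return noiseless + rng.normal(0.0, spec.noise_sd, noiseless.shape)


def make_axial_phantom(spec: AxialPhantomSpec) -> tuple[ImageVolume, GroundTruth]:
    """Render an axial effusion phantom and its exact ground truth."""
    member = _ellipsoid_membership(spec)
    noiseless = np.where(member, spec.fluid_mean, spec.background_mean).astype(np.float64)
    rng = np.random.default_rng(spec.seed)
    data = _add_noise(noiseless, spec, rng)
    volume = ImageVolume(data=data, spacing=spec.spacing, slice_axis=2, orientation="axial")
    in_plane = spec.spacing[0] * spec.spacing[1]
    per_slice = tuple(float(member[:, :, s].sum() * in_plane) for s in range(spec.shape[2]))
    count = int(member.sum())
    return volume, GroundTruth(
        true_fluid_voxels=count,
        true_volume_mm3=count * float(np.prod(spec.spacing)),
        per_slice_true_areas_mm2=per_slice,
    )


def separable_axial_spec(seed: int = 0, contrast_to_noise: float | None = None) -> AxialPhantomSpec:
    """Separable preset: contrast fixed at 160, noise set from contrast/noise ratio."""
    noise_sd = 0.0 if contrast_to_noise is None else 160.0 / contrast_to_noise
    return AxialPhantomSpec(noise_sd=noise_sd, seed=seed)


# ---------------------------------------------------------------------------
# Sagittal phantom


def _rect_roi(slice_index: int, r0: int, r1: int, c0: int, c1: int) -> PolygonROI:
    """Rectangle whose interior covers voxel centers r0..r1 x c0..c1 exactly."""
    return PolygonROI(
        slice_index=slice_index,
        vertices=(
            (r0 - 0.5, c0 - 0.5),
            (r0 - 0.5, c1 + 0.5),
            (r1 + 0.5, c1 + 0.5),
            (r1 + 0.5, c0 - 0.5),
        ),
    )


@dataclass(frozen=True)
class SagittalPhantomSpec:
    """Sagittal Hoffa phantom: fat block, homogeneous reference, seeded ROIs.

    ``per_roi_fractions`` gives, for each assessed slice (offsets -3, -1, +1,
    +3 from the patellar center), the fraction of its fat-pad ROI voxels set
    hyperintense (fat_mean + bright_offset).  fraction x ROI size must be an
    integer so the ground-truth count is exact.
    """

    shape: tuple[int, int, int] = (80, 80, 32)
    spacing: tuple[float, float, float] = (0.4, 0.4, 3.0)
    background_mean: float = 30.0
    fat_mean: float = 120.0
    bright_offset: float = 80.0
    noise_sd: float = 0.0
    center_slice_i: int = 16
    offsets: tuple[int, ...] = (-3, -1, 1, 3)
    per_roi_fractions: tuple[float, ...] = (0.3, 0.2, 0.2, 0.3)
    roi_rows: tuple[int, int] = (45, 60)
    roi_cols: tuple[int, int] = (25, 44)
    reference_rows: tuple[int, int] = (15, 24)
    reference_cols: tuple[int, int] = (30, 49)
    noise_model: str = "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.per_roi_fractions) != len(self.offsets):
            raise ValueError("need one fraction per offset")
        for f in self.per_roi_fractions:
            if not 0 <= f <= 1:
                raise ValueError(f"fractions must be in [0, 1], got {f}")
        lo = self.center_slice_i + min(self.offsets)
        hi = self.center_slice_i + max(self.offsets)
        if lo < 0 or hi >= self.shape[2]:
            raise ValueError("center_slice_i + offsets fall outside the stack")

    @property
    def roi_n_voxels(self) -> int:
        return (self.roi_rows[1] - self.roi_rows[0] + 1) * (
            self.roi_cols[1] - self.roi_cols[0] + 1
        )


def make_sagittal_phantom(
    spec: SagittalPhantomSpec,
) -> tuple[ImageVolume, GroundTruth, PolygonROI, tuple[PolygonROI, ...]]:
    """Render a sagittal Hoffa phantom.

    Returns the volume, the ground truth (per-ROI hyperintense counts), the
    reference ROI (homogeneous on the noiseless image) and the four fat-pad
    ROIs on slices center + offset.
    """
    nz = spec.shape[2]
    noiseless = np.full(spec.shape, spec.background_mean, dtype=np.float64)
    # fat block spanning all slices; ROIs and reference live inside it
    fr0 = min(spec.roi_rows[0], spec.reference_rows[0]) - 5
    fr1 = max(spec.roi_rows[1], spec.reference_rows[1]) + 5
    fc0 = min(spec.roi_cols[0], spec.reference_cols[0]) - 5
    fc1 = max(spec.roi_cols[1], spec.reference_cols[1]) + 5
    fr0, fc0 = max(fr0, 0), max(fc0, 0)
    fr1, fc1 = min(fr1, spec.shape[0] - 1), min(fc1, spec.shape[1] - 1)
    noiseless[fr0 : fr1 + 1, fc0 : fc1 + 1, :] = spec.fat_mean

    rng = np.random.default_rng(spec.seed)
    n_roi = spec.roi_n_voxels
    rois = []
    counts = []
    for offset, fraction in zip(spec.offsets, spec.per_roi_fractions):
        s = spec.center_slice_i + offset
        target = fraction * n_roi
        count = round(target)
        if abs(target - count) > 1e-9:
            raise ValueError(
                f"fraction {fraction} x {n_roi} ROI voxels is not an integer count"
            )
        roi = _rect_roi(s, *spec.roi_rows, *spec.roi_cols)
        rois.append(roi)
        counts.append(count)
        if count:
            flat = rng.choice(n_roi, size=count, replace=False)
            rr = spec.roi_rows[0] + flat // (spec.roi_cols[1] - spec.roi_cols[0] + 1)
            cc = spec.roi_cols[0] + flat % (spec.roi_cols[1] - spec.roi_cols[0] + 1)
            noiseless[rr, cc, s] = spec.fat_mean + spec.bright_offset

    data = _add_noise(noiseless, spec, rng)
    volume = ImageVolume(data=data, spacing=spec.spacing, slice_axis=2, orientation="sagittal")
    reference_roi = _rect_roi(spec.center_slice_i, *spec.reference_rows, *spec.reference_cols)
    vv = float(np.prod(spec.spacing))
    total = int(sum(counts))
    truth = GroundTruth(
        true_fluid_voxels=total,
        true_volume_mm3=total * vv,
        per_roi_supra_counts=tuple(counts),
    )
    return volume, truth, reference_roi, tuple(rois)


def default_sagittal_spec(seed: int = 0, **kwargs) -> SagittalPhantomSpec:
    return SagittalPhantomSpec(seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# Cohort simulation


@dataclass(frozen=True)
class ReaderModel:
    """Per-reader multiplicative bias plus multiplicative and additive noise."""

    biases: tuple[float, ...] = (1.0, 1.03)
    noise_cv: float = 0.06
    additive_sd_mm3: float = 0.0

    def measure(self, true_value: np.ndarray, reader: int, rng: np.random.Generator) -> np.ndarray:
        out = true_value * self.biases[reader]
        if self.noise_cv > 0:
            out = out * np.exp(rng.normal(0.0, self.noise_cv, true_value.shape))
        if self.additive_sd_mm3 > 0:
            out = out + rng.normal(0.0, self.additive_sd_mm3, true_value.shape)
        return np.maximum(out, 0.0)


@dataclass(frozen=True)
class CohortModel:
    """Generative model linking grades, groups, true volumes and reads.

    Grade frequencies default to the effusion and Hoffa grade distributions
    of a 301-knee osteoarthritis progression cohort (111/131/53/6 and
    139/135/24/3).  Grade-to-volume means are monotone, on the scale of
    suprapatellar effusion volumes in mm^3; radiographic/pain progression
    applies weak multiplicative effects so that case-control discrimination
    is modest (AUC in the 0.55-0.60 range) rather than trivial.
    """

    group_sizes: tuple[int, int, int, int] = (97, 52, 52, 100)
    grade_weights_es: tuple[float, ...] = (111, 131, 53, 6)
    grade_weights_hs: tuple[float, ...] = (139, 135, 24, 3)
    grade_volume_means_es: tuple[float, ...] = (2000.0, 6000.0, 12000.0, 20000.0)
    grade_volume_means_hs: tuple[float, ...] = (50.0, 250.0, 700.0, 1400.0)
    volume_sigma_log: float = 0.45
    radiographic_effect: float = 0.25  # multiplicative lift for groups 1 and 2
    pain_effect: float = 0.05          # multiplicative lift for groups 1 and 3
    reader_model: ReaderModel = field(default_factory=ReaderModel)
    n_slices_range: tuple[int, int] = (10, 16)
    max_es_volume_mm3: float = 40000.0

    def __post_init__(self) -> None:
        es_const = len(set(self.grade_volume_means_es)) == 1
        hs_const = len(set(self.grade_volume_means_hs)) == 1
        if (
            self.volume_sigma_log == 0
            and es_const
            and hs_const
            and self.radiographic_effect == 0
            and self.pain_effect == 0
        ):
            raise ValueError("degenerate cohort model: zero variance everywhere")


def _axial_spec_for_volume(target_mm3: float, seed: int) -> AxialPhantomSpec:
    """An axial spec whose ellipsoid has (approximately) the target volume.

    Semi-axes are (a, a, 0.6a) with 4/3 pi a^2 c equal to the target; the
    exact ground truth is the digitized voxel-center count.
    """
    a = (3.0 * target_mm3 / (4.0 * math.pi * 0.6)) ** (1.0 / 3.0)
    shape = (128, 128, 32)
    spacing = (0.5, 0.5, 1.5)
    center = tuple(((n - 1) * d) / 2.0 for n, d in zip(shape, spacing))
    return AxialPhantomSpec(
        shape=shape,
        spacing=spacing,
        ellipsoid_center_mm=center,
        ellipsoid_semi_axes_mm=(a, a, 0.6 * a),
        patella_range=SliceRange(0, 31),
        seed=seed,
    )


def _digitized_count(spec: AxialPhantomSpec) -> int:
    return int(_ellipsoid_membership(spec).sum())


def _reliability_subset(
    grades: np.ndarray, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Indices of a subset weighted toward a uniform grade distribution."""
    levels = np.unique(grades)
    per = size // len(levels)
    chosen: list[int] = []
    for g in levels:
        pool = np.flatnonzero(grades == g)
        take = min(per, pool.size)
        chosen.extend(rng.choice(pool, size=take, replace=False))
    remaining = np.setdiff1d(np.arange(grades.size), np.array(chosen, dtype=int))
    extra = size - len(chosen)
    if extra > 0:
        chosen.extend(rng.choice(remaining, size=extra, replace=False))
    return np.sort(np.array(chosen[:size], dtype=int))


def simulate_cohort(
    n: int = 301,
    model: CohortModel | None = None,
    seed: int = 0,
    reliability_n: int = 30,
):
    """Simulate a case-control cohort of knees with known ground truth.

    Returns ``(phantom_specs, cohort, ground_truth)``:

    * ``phantom_specs`` — one :class:`AxialPhantomSpec` per knee whose
      digitized ellipsoid volume is the knee's true effusion volume (any of
      them can be rendered with :func:`make_axial_phantom`);
    * ``cohort`` — a :class:`~synovolume.validation_stats.CohortTable` with
      one row per (knee, reader, session): all knees are read once by reader
      1, and a reliability subset (grade-balanced, ``reliability_n`` knees)
      is additionally re-read by reader 1 and read by reader 2;
    * ``ground_truth`` — a DataFrame of per-knee true volumes, grades,
      groups and slice counts.

    Group sizes are exact (default 97/52/52/100); deterministic per seed.
    """
    from .validation_stats import CohortTable

    if n < 20:
        raise ValueError("cohort simulation needs n >= 20")
    model = model or CohortModel()
    rng = np.random.default_rng(seed)

    sizes = np.asarray(model.group_sizes, dtype=int)
    if sizes.sum() != n:
        # rescale the default proportions to the requested n, exact total
        scaled = np.floor(sizes * n / sizes.sum()).astype(int)
        while scaled.sum() < n:
            scaled[int(np.argmax(sizes * n / sizes.sum() - scaled))] += 1
        sizes = scaled
    groups = np.repeat([1, 2, 3, 4], sizes)
    rng.shuffle(groups)

    def draw_grades(weights: Sequence[float]) -> np.ndarray:
        p = np.asarray(weights, dtype=float)
        return rng.choice(len(p), size=n, p=p / p.sum())

    grade_es = draw_grades(model.grade_weights_es)
    grade_hs = draw_grades(model.grade_weights_hs)

    rad = np.isin(groups, [1, 2]).astype(float)
    pain = np.isin(groups, [1, 3]).astype(float)
    lift = (1.0 + model.radiographic_effect * rad) * (1.0 + model.pain_effect * pain)

    means_es = np.asarray(model.grade_volume_means_es, dtype=float)[grade_es]
    target_es = means_es * np.exp(rng.normal(0.0, model.volume_sigma_log, n)) * lift
    target_es = np.clip(target_es, 100.0, model.max_es_volume_mm3)

    means_hs = np.asarray(model.grade_volume_means_hs, dtype=float)[grade_hs]
    target_hs = means_hs * np.exp(rng.normal(0.0, model.volume_sigma_log, n)) * lift
    target_hs = np.maximum(target_hs, 0.0)

    # digitize the ES targets through actual phantom geometry
    specs = []
    true_es = np.empty(n)
    voxel_vol_axial = 0.5 * 0.5 * 1.5
    for i in range(n):
        spec = _axial_spec_for_volume(float(target_es[i]), seed=int(rng.integers(0, 2**31)))
        specs.append(spec)
        true_es[i] = _digitized_count(spec) * voxel_vol_axial
    voxel_vol_sag = 0.4 * 0.4 * 3.0
    true_hs = np.round(target_hs / voxel_vol_sag) * voxel_vol_sag

    n_slices = rng.integers(model.n_slices_range[0], model.n_slices_range[1] + 1, size=n)

    truth = pd.DataFrame(
        {
            "knee_id": np.arange(n),
            "grade_es": grade_es,
            "grade_hs": grade_hs,
            "group": groups,
            "true_v_eff_mm3": true_es,
            "true_x_hoff_mm3": true_hs,
            "n_slices": n_slices,
        }
    )

    rel_idx = _reliability_subset(grade_es, min(reliability_n, n), rng)
    reads = [(0, np.arange(n), 1, 1)]  # (reader index, knees, reader_id, session_id)
    reads.append((0, rel_idx, 1, 2))
    reads.append((1, rel_idx, 2, 1))

    rows = []
    rm = model.reader_model
    for reader_idx, idx, reader_id, session_id in reads:
        v_eff = rm.measure(true_es[idx], reader_idx, rng)
        x_hoff = rm.measure(true_hs[idx], reader_idx, rng)
        rows.append(
            pd.DataFrame(
                {
                    "knee_id": idx,
                    "reader_id": reader_id,
                    "session_id": session_id,
                    "v_eff_mm3": v_eff,
                    "v_norm_mm3_per_slice": v_eff / n_slices[idx],
                    "x_hoff_mm3": x_hoff,
                    "grade": grade_es[idx],
                    "grade_hs": grade_hs[idx],
                    "group": groups[idx],
                }
            )
        )
    cohort = CohortTable(pd.concat(rows, ignore_index=True))
    return specs, cohort, truth
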