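"""Volume and mask data model, coordinate conventions, and file I/O.

Conventions used throughout the package:

* All indices are 0-based.  Slice ranges are inclusive on both ends, so the
  number of slices in a range is ``last - first + 1``.
* Volumes are 3-D scalar grids with per-axis voxel spacing in millimetres;
  volumes are always reported in mm^3 and derived strictly from the header
  spacing.
* A voxel belongs to a polygonal ROI iff its *center* lies inside the polygon
  or on its boundary.  This single rasterization convention is applied
  everywhere so that repeated reads are not polluted by rasterization ties.
* Axis roles (which array axis is the slice axis, and whether the stack is
  axial or sagittal) are metadata set by the caller or the file reader; they
  are never inferred from intensity content.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pydicom
import shapely

__all__ = [
    "ImageVolume",
    "SliceRange",
    "BinaryMask",
    "PolygonROI",
    "InputError",
    "FormatError",
    "read_volume",
    "write_volume",
    "write_mask",
    "read_mask",
    "mask_volume_mm3",
    "rasterize_roi",
]


class InputError(ValueError):
    """A required input file is missing or unreadable."""


class FormatError(ValueError):
    """An input file or series violates its format contract."""


@dataclass(frozen=True)
class ImageVolume:
    """A 3-D grayscale MR volume with voxel-spacing and axis-role metadata.

    Parameters
    ----------
    data
        3-D array of non-negative scalar intensities (arbitrary MR units).
    spacing
        ``(d0, d1, d2)`` voxel edge lengths in mm, one per array axis.
    slice_axis
        The array axis along which anatomical slices are stacked
        (superior-inferior for an axial stack, left-right for a sagittal
        stack).  Defaults to the last axis.
    orientation
        Optional free-text role label, e.g. ``"axial"`` or ``"sagittal"``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    slice_axis: int = 2
    orientation: str | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"volume must be 3-D, got ndim={data.ndim}")
        object.__setattr__(self, "data", data)
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        object.__setattr__(self, "spacing", spacing)
        if self.slice_axis not in (0, 1, 2):
            raise ValueError(f"slice_axis must be 0, 1 or 2, got {self.slice_axis}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_slices(self) -> int:
        return self.data.shape[self.slice_axis]

    @property
    def voxel_volume_mm3(self) -> float:
        """dx*dy*dz in mm^3; invariant under axis permutation."""
        return float(np.prod(self.spacing))

    @property
    def in_plane_area_mm2(self) -> float:
        """Area of one voxel face within a slice plane."""
        d = [s for ax, s in enumerate(self.spacing) if ax != self.slice_axis]
        return float(d[0] * d[1])

    @property
    def slice_thickness_mm(self) -> float:
        return self.spacing[self.slice_axis]

    def get_slice(self, index: int) -> np.ndarray:
        """Return the 2-D in-plane image at a slice index."""
        if not 0 <= index < self.n_slices:
            raise ValueError(f"slice index {index} out of bounds for {self.n_slices} slices")
        return np.take(self.data, index, axis=self.slice_axis)


@dataclass(frozen=True)
class SliceRange:
    """An inclusive range [first, last] of 0-based slice indices."""

    first: int
    last: int

    def __post_init__(self) -> None:
        if not 0 <= self.first <= self.last:
            raise ValueError(f"require 0 <= first <= last, got [{self.first}, {self.last}]")

    @property
    def count(self) -> int:
        return self.last - self.first + 1

    @property
    def indices(self) -> range:
        return range(self.first, self.last + 1)

    def validate_for(self, volume: ImageVolume) -> None:
        if self.last >= volume.n_slices:
            raise ValueError(
                f"slice range [{self.first}, {self.last}] exceeds volume with "
                f"{volume.n_slices} slices"
            )


@dataclass
class BinaryMask:
    """A boolean grid congruent with an :class:`ImageVolume`."""

    voxels: np.ndarray
    slice_axis: int = 2

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be 3-D")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def count(self) -> int:
        return int(self.voxels.sum())

    def slice_counts(self) -> np.ndarray:
        """True-voxel count per slice along the slice axis."""
        other = tuple(ax for ax in range(3) if ax != self.slice_axis)
        return self.voxels.sum(axis=other)


@dataclass(frozen=True)
class PolygonROI:
    """A simple polygon drawn on one slice, vertices in (row, col) voxel units.

    Voxel (r, c) has its center at coordinates (r, c): vertex coordinates are
    expressed on the voxel-index grid, and fractional coordinates lie between
    voxel centers.
    """

    slice_index: int
    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        verts = tuple((float(r), float(c)) for r, c in self.vertices)
        if len(verts) < 3:
            raise ValueError(f"polygon needs >= 3 vertices, got {len(verts)}")
        object.__setattr__(self, "vertices", verts)
        if self.slice_index < 0:
            raise ValueError("slice_index must be non-negative")
        poly = self.to_shapely()
        if not poly.is_valid or poly.area == 0:
            raise ValueError("polygon must be simple (non-self-intersecting) with positive area")

    def to_shapely(self) -> shapely.Polygon:
        return shapely.Polygon(self.vertices)

    def rasterize_slice(self, shape2d: tuple[int, int]) -> np.ndarray:
        """Boolean 2-D mask: True where the voxel center is inside/on the polygon."""
        poly = self.to_shapely()
        rmin = max(0, int(np.floor(poly.bounds[0])))
        rmax = min(shape2d[0] - 1, int(np.ceil(poly.bounds[2])))
        cmin = max(0, int(np.floor(poly.bounds[1])))
        cmax = min(shape2d[1] - 1, int(np.ceil(poly.bounds[3])))
        out = np.zeros(shape2d, dtype=bool)
        if rmax < rmin or cmax < cmin:
            return out
        rr, cc = np.meshgrid(
            np.arange(rmin, rmax + 1), np.arange(cmin, cmax + 1), indexing="ij"
        )
        # covers == inside or on boundary; for points this equals intersects
        hit = shapely.intersects_xy(poly, rr.ravel(), cc.ravel())
        out[rr.ravel()[hit], cc.ravel()[hit]] = True
        return out

    def to_json(self) -> str:
        return json.dumps(
            {"slice_index": self.slice_index, "vertices": [list(v) for v in self.vertices]}
        )

    @classmethod
    def from_json(cls, text: str) -> "PolygonROI":
        obj = json.loads(text)
        return cls(slice_index=obj["slice_index"], vertices=tuple(map(tuple, obj["vertices"])))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "PolygonROI":
        p = Path(path)
        if not p.exists():
            raise InputError(f"ROI file not found: {p}")
        return cls.from_json(p.read_text())


# ---------------------------------------------------------------------------
# File I/O


def _read_nifti(path: Path) -> ImageVolume:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several error types
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    return ImageVolume(data=data, spacing=tuple(float(z) for z in zooms))


def _read_dicom_dir(path: Path, spacing_tol_mm: float = 1e-3) -> ImageVolume:
    files = sorted(p for p in path.iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue  # skip non-DICOM files (e.g. DICOMDIR, manifests)
        if hasattr(ds, "pixel_array"):
            datasets.append(ds)
    if not datasets:
        raise InputError(f"no readable DICOM slices in {path}")
    try:
        datasets.sort(key=lambda d: int(d.InstanceNumber))
    except AttributeError as exc:
        raise FormatError(f"{path}: DICOM slices lack InstanceNumber") from exc

    numbers = [int(d.InstanceNumber) for d in datasets]
    expected = list(range(numbers[0], numbers[0] + len(numbers)))
    if numbers != expected:
        missing = sorted(set(expected) - set(numbers))
        raise FormatError(
            f"{path}: DICOM series has non-contiguous instance numbers "
            f"(missing {missing or numbers})"
        )

    ref = datasets[0]
    px = [float(v) for v in ref.PixelSpacing]
    for d in datasets[1:]:
        if any(abs(float(a) - b) > spacing_tol_mm for a, b in zip(d.PixelSpacing, px)):
            raise FormatError(f"{path}: in-plane spacing inconsistent beyond {spacing_tol_mm} mm")

    # slice spacing: prefer the spacing between image positions, fall back to
    # SpacingBetweenSlices / SliceThickness for single- or position-less series
    dz = None
    if len(datasets) > 1 and hasattr(ref, "ImagePositionPatient"):
        pos = np.array([[float(v) for v in d.ImagePositionPatient] for d in datasets])
        steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        if steps.size and float(steps.max() - steps.min()) > spacing_tol_mm:
            raise FormatError(f"{path}: slice spacing inconsistent beyond {spacing_tol_mm} mm")
        if steps.size:
            dz = float(steps.mean())
    if dz is None:
        dz = float(getattr(ref, "SpacingBetweenSlices", getattr(ref, "SliceThickness", 1.0)))

    data = np.stack([d.pixel_array.astype(np.float64) for d in datasets], axis=2)
    return ImageVolume(data=data, spacing=(px[0], px[1], dz))


def read_volume(
    path: str | Path,
    format: str | None = None,
    *,
    slice_axis: int | None = None,
    orientation: str | None = None,
) -> ImageVolume:
    """Read a 3-D volume from a NIfTI file or a DICOM series directory.

    ``format`` is ``"nifti"`` or ``"dicom_dir"``; when omitted it is chosen
    from the path (directory -> DICOM series, file -> NIfTI).  ``slice_axis``
    and ``orientation`` override the defaults recorded on the returned volume.
    """
    p = Path(path)
    if not p.exists():
        raise InputError(f"input path does not exist: {p}")
    if format is None:
        format = "dicom_dir" if p.is_dir() else "nifti"
    if format == "nifti":
        vol = _read_nifti(p)
    elif format == "dicom_dir":
        if not p.is_dir():
            raise InputError(f"dicom_dir format requires a directory, got {p}")
        vol = _read_dicom_dir(p)
    else:
        raise ValueError(f"unknown format {format!r}")
    if slice_axis is not None or orientation is not None:
        vol = ImageVolume(
            data=vol.data,
            spacing=vol.spacing,
            slice_axis=vol.slice_axis if slice_axis is None else slice_axis,
            orientation=orientation,
        )
    return vol


def write_volume(volume: ImageVolume, path: str | Path) -> None:
    """Write a volume as NIfTI-1 with a diagonal affine built from the spacing."""
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float64), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def write_mask(mask: BinaryMask, spacing: Sequence[float], path: str | Path) -> None:
    """Write a binary mask as 8-bit 0/1 NIfTI-1."""
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), affine)
    img.header.set_zooms(tuple(spacing))
    nib.save(img, str(path))


def read_mask(path: str | Path, slice_axis: int = 2) -> BinaryMask:
    p = Path(path)
    if not p.exists():
        raise InputError(f"input path does not exist: {p}")
    img = nib.load(str(p))
    return BinaryMask(voxels=np.asarray(img.get_fdata()) > 0.5, slice_axis=slice_axis)


# ---------------------------------------------------------------------------
# Geometry


def mask_volume_mm3(mask: BinaryMask, spacing: Sequence[float]) -> float:
    """Volume of a mask: (number of true voxels) x dx*dy*dz.

    Additive over disjoint masks and linear in voxel count.
    """
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ValueError("spacing must have three components")
    return mask.count() * float(np.prod(spacing))


def rasterize_roi(roi: PolygonROI, volume: ImageVolume) -> BinaryMask:
    """Rasterize a polygon ROI into a volume-congruent binary mask.

    The mask is True exactly on ``roi.slice_index`` for voxels whose center
    lies inside or on the polygon; every other slice is False.
    """
    if roi.slice_index >= volume.n_slices:
        raise ValueError(
            f"ROI slice {roi.slice_index} out of bounds for {volume.n_slices} slices"
        )
    shape2d = volume.get_slice(roi.slice_index).shape
    plane = roi.rasterize_slice(shape2d)
    voxels = np.zeros(volume.shape, dtype=bool)
    idx: list[slice | int] = [slice(None)] * 3
    idx[volume.slice_axis] = roi.slice_index
    voxels[tuple(idx)] = plane
    return BinaryMask(voxels=voxels, slice_axis=volume.slice_axis)
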