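"""Core data containers shared across the pipeline.

All volumes use a single coordinate convention: axis 0 is the scan (slice)
axis with index 0 most cranial, axes 1 and 2 are image rows and columns.
Physical spacing is carried alongside the voxel data so that areas and
volumes are always computed in mm² / mm³ and reported in cm³.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

__all__ = [
    "ScanVolume",
    "MaskVolume",
    "AreaProfile",
    "ConfinedRegion",
    "AxialMeasurements",
    "VolumeEstimate",
    "GeometryError",
    "MetadataError",
    "DegenerateScanError",
    "LabelingError",
    "EmptyPredictionError",
    "TrainingDivergedError",
]


class GeometryError(ValueError):
    """Phantom geometry violates a containment constraint."""


class MetadataError(ValueError):
    """Required spacing/position metadata missing or inconsistent."""


class DegenerateScanError(ValueError):
    """Scan has no separable body or zero intensity variance."""


class LabelingError(ValueError):
    """Outlined boundary is not a closed curve; fill would leak."""


class EmptyPredictionError(ValueError):
    """An operation requiring a nonempty prediction received an empty one."""


class TrainingDivergedError(RuntimeError):
    """Training produced a non-finite loss."""


@dataclass
class ScanVolume:
    """Ordered stack of axial intensity slices with physical spacing.

    Parameters
    ----------
    voxels : ndarray, shape (n_slices, rows, cols)
        Intensity data; integer (raw scanner-like units) or float
        (after normalization).
    pixel_spacing : (float, float)
        In-plane spacing in mm per pixel, (row, col) order — the DICOM
        PixelSpacing pair and the source of the pixel-area conversion
        factor.
    slice_spacing : float
        Nominal inter-slice distance in mm (DICOM SliceThickness for
        contiguous acquisitions).
    slice_positions : ndarray, shape (n_slices,)
        Physical position of each slice along the scan axis in mm,
        strictly monotonic; the depth coordinate of the trapezoidal
        volume integration.
    """

    voxels: np.ndarray
    pixel_spacing: tuple[float, float]
    slice_spacing: float
    slice_positions: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3-D, got shape {self.voxels.shape}")
        rs, cs = self.pixel_spacing
        if rs <= 0 or cs <= 0 or self.slice_spacing <= 0:
            raise MetadataError("all spacings must be > 0")
        if self.slice_positions is None:
            self.slice_positions = np.arange(self.voxels.shape[0], dtype=float) * self.slice_spacing
        self.slice_positions = np.asarray(self.slice_positions, dtype=float)
        if self.slice_positions.shape != (self.voxels.shape[0],):
            raise MetadataError("slice_positions length must equal number of slices")
        if self.voxels.shape[0] > 1:
            diffs = np.diff(self.slice_positions)
            if not (np.all(diffs > 0) or np.all(diffs < 0)):
                raise MetadataError("slice_positions must be strictly monotonic")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def pixel_area_mm2(self) -> float:
        """Pixel size conversion factor: physical area of one pixel in mm²."""
        return float(self.pixel_spacing[0] * self.pixel_spacing[1])

    def copy(self) -> "ScanVolume":
        return replace(self, voxels=self.voxels.copy(), slice_positions=self.slice_positions.copy())


MaskRole = Literal["GT", "MP_raw", "MP_pp", "body", "generic"]


@dataclass
class MaskVolume:
    """Binary voxel stack aligned to a :class:`ScanVolume`.

    The ``role`` tag records provenance — ground truth (GT), raw model
    prediction (MP_raw) or post-processed prediction (MP_pp) — and is
    informational only; all operations treat the mask uniformly.
    """

    voxels: np.ndarray
    role: MaskRole = "generic"

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError(f"mask voxels must be 3-D, got shape {vox.shape}")
        uniq = np.unique(vox)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be in {0, 1}")
        self.voxels = vox.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    def copy(self, role: MaskRole | None = None) -> "MaskVolume":
        return MaskVolume(self.voxels.copy(), role=role or self.role)

    def foreground_slices(self) -> np.ndarray:
        """Indices of slices containing at least one foreground pixel."""
        return np.flatnonzero(self.voxels.any(axis=(1, 2)))


@dataclass
class AreaProfile:
    """Per-slice segmented area (mm²) along the scan axis."""

    areas: np.ndarray
    slice_positions: np.ndarray

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        self.slice_positions = np.asarray(self.slice_positions, dtype=float)
        if self.areas.ndim != 1 or self.areas.shape != self.slice_positions.shape:
            raise ValueError("areas and slice_positions must be 1-D and equal length")
        if np.any(self.areas < 0):
            raise ValueError("areas must be >= 0")

    def __len__(self) -> int:
        return self.areas.size


@dataclass(frozen=True)
class ConfinedRegion:
    """Closed slice-index interval [left_index, right_index] bounding the spleen."""

    left_index: int
    right_index: int

    def __post_init__(self) -> None:
        if self.left_index > self.right_index:
            raise ValueError("left_index must be <= right_index")
        if self.left_index < 0:
            raise ValueError("indices must be >= 0")

    def contains(self, index: int) -> bool:
        return self.left_index <= index <= self.right_index


@dataclass(frozen=True)
class AxialMeasurements:
    """The three radiologist distances feeding the volume formula, in cm.

    L — craniocaudal span between the first and last axial slices showing
    the spleen; D — largest in-plane long-axis diameter over all slices;
    T — largest extent perpendicular to the D chord, measured in the slice
    where D is attained.  ``d_slice_index`` records that slice.
    """

    L: float
    D: float
    T: float
    d_slice_index: int = -1

    def __post_init__(self) -> None:
        if self.L < 0 or self.D < 0 or self.T < 0:
            raise ValueError("axial measurements must be >= 0")
        if self.T > self.D + 1e-9:
            raise ValueError("T cannot exceed D (perpendicular extent bound)")


VolumeMethod = Literal["GT", "formula", "MP", "MP_FS"]


@dataclass(frozen=True)
class VolumeEstimate:
    """A spleen volume in cm³ tagged with the method that produced it."""

    value: float
    method: VolumeMethod = "GT"

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("volume must be >= 0")
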