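"""Voxel grids with physical geometry.

The internal axis order is fixed as (x, y, z): ``data[i, j, k]`` is the
voxel at physical position ``origin + (i*sx, j*sy, k*sz)``. Readers for
formats with a different native order (DICOM, TIFF stacks, MetaImage
arrays) transpose on load so anisotropic spacing can never be silently
attached to the wrong axis. Indices are 0-based and physical coordinates
refer to voxel centers.

Physical lengths carry an explicit unit tag, either ``"um"`` or ``"mm"``;
every downstream quantity (radii, arc lengths, volumes) inherits it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DataError

#: supported length-unit tags
UNITS = ("um", "mm")

#: microliters per cubic unit (1 ul = 1 mm^3 = 1e9 um^3)
UL_PER_CUBIC_UNIT = {"mm": 1.0, "um": 1e-9}

#: millimeters per unit
MM_PER_UNIT = {"mm": 1.0, "um": 1e-3}


def _validate_geometry(shape, spacing, unit):
    if len(shape) != 3 or any(s < 1 for s in shape):
        raise DataError(f"volume must be 3D with each axis >= 1, got shape {shape}")
    spacing = np.asarray(spacing, dtype=float)
    if spacing.shape != (3,) or not np.all(np.isfinite(spacing)) or np.any(spacing <= 0):
        raise DataError(f"spacing must be 3 strictly positive finite numbers, got {spacing}")
    if unit not in UNITS:
        raise DataError(f"unit must be one of {UNITS}, got {unit!r}")
    return tuple(spacing)


@dataclass
class VoxelGrid:
    """A 3D scalar image with anisotropy-aware physical spacing.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar intensities (arbitrary CT units or HU).
    spacing : (sx, sy, sz)
        Physical edge length of one voxel along each axis, in `unit`.
    origin : (ox, oy, oz)
        Physical coordinate of the center of voxel (0, 0, 0).
    unit : {"um", "mm"}
        Length unit for spacing, origin and all derived quantities.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    unit: str = "mm"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.spacing = _validate_geometry(self.data.shape, self.spacing, self.unit)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in cubic `unit`."""
        return float(np.prod(self.spacing))

    def index_to_physical(self, index) -> np.ndarray:
        """Physical coordinate(s) of voxel index/indices (centers)."""
        idx = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def physical_to_index(self, point) -> np.ndarray:
        """Continuous voxel index of physical coordinate(s)."""
        p = np.asarray(point, dtype=float)
        return (p - np.asarray(self.origin)) / np.asarray(self.spacing)

    def with_data(self, data: np.ndarray) -> "VoxelGrid":
        """New grid sharing this grid's geometry with different voxel data."""
        return replace(self, data=data)


@dataclass
class BinaryMask:
    """A boolean segmentation sharing a source grid's geometry."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    unit: str = "mm"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        self.spacing = _validate_geometry(self.data.shape, self.spacing, self.unit)
        self.origin = tuple(float(o) for o in self.origin)

    @classmethod
    def like(cls, grid: VoxelGrid | "BinaryMask", data: np.ndarray) -> "BinaryMask":
        if np.asarray(data).shape != grid.data.shape:
            raise DataError("mask shape must match source grid shape")
        return cls(data=data, spacing=grid.spacing, origin=grid.origin, unit=grid.unit)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def foreground_count(self) -> int:
        return int(self.data.sum())

    index_to_physical = VoxelGrid.index_to_physical
    physical_to_index = VoxelGrid.physical_to_index
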