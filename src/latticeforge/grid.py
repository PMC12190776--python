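"""Axis-aligned voxel grids, binary structure masks and dose fields.

Geometry convention used throughout the package: a grid is an axis-aligned
raster of ``shape = (nx, ny, nz)`` voxels with per-axis ``spacing`` in mm
(anisotropic allowed) and a world-space ``origin``.  The *center* of voxel
``(i, j, k)`` (0-based) sits at ``origin + (i*sx, j*sy, k*sz)`` mm.  Masks
are boolean fields over a grid; dose fields are non-negative Gy values.
Two rasters are composable only when their grids are identical — there is
no implicit resampling.

All morphology (margin dilation/erosion, distance-to-boundary) is metric:
exact Euclidean distance transforms in mm that honor anisotropic spacing,
so a statement like "this sphere lies entirely within the target" has an
unambiguous meaning independent of voxel size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DomainError, GridMismatchError, ParameterError

__all__ = [
    "VoxelGrid",
    "Mask",
    "DoseGrid",
    "volume_cc",
    "dilate_mask",
    "erode_mask",
    "mask_union",
    "mask_intersection",
    "mask_difference",
    "mask_complement",
    "distance_to_boundary",
    "distance_to_mask",
    "set_voxel_centers",
    "centroid",
]

_EPS_MM = 1e-9


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned 3D raster geometry (voxel counts, mm spacing, world origin)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(shape) != 3 or len(spacing) != 3 or len(origin) != 3:
            raise ParameterError("VoxelGrid requires 3D shape, spacing and origin")
        if any(n < 1 for n in shape):
            raise ParameterError(f"all shape entries must be >= 1, got {shape}")
        if any(not np.isfinite(s) or s <= 0 for s in spacing):
            raise ParameterError(f"all spacings must be positive, got {spacing}")
        if any(not np.isfinite(o) for o in origin):
            raise ParameterError(f"origin must be finite, got {origin}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    def axis_coords(self, axis: int) -> np.ndarray:
        """World-mm coordinates of voxel centers along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices ``(..., 3)`` to world mm."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Map world-mm points ``(..., 3)`` to fractional voxel indices."""
        pts = np.asarray(pts, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)


def _check_same_grid(a, b) -> None:
    if a.grid != b.grid:
        raise GridMismatchError(
            f"operands live on different grids: {a.grid} vs {b.grid}"
        )


@dataclass
class Mask:
    """Binary structure mask on a :class:`VoxelGrid`."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.shape != self.grid.shape:
            raise ParameterError(
                f"mask shape {values.shape} != grid shape {self.grid.shape}"
            )
        self.values = values.astype(bool, copy=False)

    @property
    def count(self) -> int:
        return int(self.values.sum())

    @property
    def is_empty(self) -> bool:
        return not self.values.any()

    def copy(self) -> "Mask":
        return Mask(self.grid, self.values.copy())

    # voxelwise boolean algebra -------------------------------------------
    def __or__(self, other: "Mask") -> "Mask":
        return mask_union(self, other)

    def __and__(self, other: "Mask") -> "Mask":
        return mask_intersection(self, other)

    def __sub__(self, other: "Mask") -> "Mask":
        return mask_difference(self, other)

    def __invert__(self) -> "Mask":
        return mask_complement(self)

    def contains(self, other: "Mask") -> bool:
        """True iff ``other`` ⊆ ``self`` voxelwise."""
        _check_same_grid(self, other)
        return bool(np.all(self.values | ~other.values))


@dataclass
class DoseGrid:
    """Dose field in Gy on a :class:`VoxelGrid`; finite and non-negative."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != self.grid.shape:
            raise ParameterError(
                f"dose shape {values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise ParameterError("dose values must be finite")
        if np.any(values < 0):
            raise ParameterError("dose values must be non-negative (Gy)")
        self.values = values

    def copy(self) -> "DoseGrid":
        return DoseGrid(self.grid, self.values.copy())


# ---------------------------------------------------------------------------
# volumes and set algebra
# ---------------------------------------------------------------------------

def volume_cc(mask: Mask) -> float:
    """Volume of a mask in cc (set voxels × voxel volume)."""
    return mask.count * mask.grid.voxel_volume_mm3 / 1000.0


def mask_union(a: Mask, b: Mask) -> Mask:
    _check_same_grid(a, b)
    return Mask(a.grid, a.values | b.values)


def mask_intersection(a: Mask, b: Mask) -> Mask:
    _check_same_grid(a, b)
    return Mask(a.grid, a.values & b.values)


def mask_difference(a: Mask, b: Mask) -> Mask:
    _check_same_grid(a, b)
    return Mask(a.grid, a.values & ~b.values)


def mask_complement(a: Mask) -> Mask:
    return Mask(a.grid, ~a.values)


# ---------------------------------------------------------------------------
# metric morphology
# ---------------------------------------------------------------------------

def distance_to_mask(mask: Mask) -> np.ndarray:
    """Euclidean distance (mm) from every voxel center to the nearest set
    voxel center; 0 on set voxels.  Empty mask → DomainError."""
    if mask.is_empty:
        raise DomainError("distance_to_mask of an empty mask is undefined")
    return ndimage.distance_transform_edt(~mask.values, sampling=mask.grid.spacing)


def distance_to_boundary(mask: Mask) -> np.ndarray:
    """For set voxels, Euclidean distance (mm) to the nearest unset voxel
    center; 0 on unset voxels.

    The world outside the grid counts as unset (the array is padded with one
    background layer before the transform), so a structure touching the grid
    edge is treated as bounded there.
    """
    if mask.is_empty:
        raise DomainError("distance_to_boundary of an empty mask is undefined")
    padded = np.pad(mask.values, 1, mode="constant", constant_values=False)
    dist = ndimage.distance_transform_edt(padded, sampling=mask.grid.spacing)
    return dist[1:-1, 1:-1, 1:-1]


def dilate_mask(mask: Mask, margin_mm: float) -> Mask:
    """Isotropic metric dilation: voxels whose center lies within
    ``margin_mm`` of some set voxel center.  Input ⊆ output."""
    if margin_mm < 0:
        raise ParameterError(f"margin must be >= 0 mm, got {margin_mm}")
    if margin_mm == 0 or mask.is_empty:
        return mask.copy()
    dist = distance_to_mask(mask)
    return Mask(mask.grid, dist <= margin_mm + _EPS_MM)


def erode_mask(mask: Mask, margin_mm: float) -> Mask:
    """Isotropic metric erosion: set voxels whose distance to the boundary
    exceeds ``margin_mm``.  Output ⊆ input."""
    if margin_mm < 0:
        raise ParameterError(f"margin must be >= 0 mm, got {margin_mm}")
    if margin_mm == 0 or mask.is_empty:
        return mask.copy()
    dist = distance_to_boundary(mask)
    return Mask(mask.grid, dist > margin_mm + _EPS_MM)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def set_voxel_centers(mask: Mask) -> np.ndarray:
    """World-mm coordinates ``(n, 3)`` of all set voxel centers."""
    idx = np.argwhere(mask.values)
    return mask.grid.index_to_world(idx)


def centroid(mask: Mask) -> np.ndarray:
    """World-mm centroid of the set voxel centers."""
    if mask.is_empty:
        raise DomainError("centroid of an empty mask is undefined")
    return set_voxel_centers(mask).mean(axis=0)
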