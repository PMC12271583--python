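"""Voxel-grid data model and coordinate/index transforms.

A :class:`VoxelGrid` is a 3-D scalar field on a regular grid with a physical
origin and (possibly anisotropic) voxel sizes, the universal in-memory map
representation of this package.  The value array is indexed ``(i, j, k)``
where ``i`` runs along z (sections), ``j`` along y (rows) and ``k`` along x
(columns) — the canonical MRC storage order.

The forward coordinate-to-index transform truncates toward minus infinity::

    i = floor((z - origin_z) / voxel_z)      (and j, k analogously for y, x)

The inverse uses the voxel-*center* convention, ``origin + (idx + 0.5) * voxel``,
so that ``coords_to_indices(indices_to_coords(idx)) == idx`` for every
in-bounds index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .exceptions import GridBoundsError, InvalidParameterError

__all__ = [
    "VoxelGrid",
    "coords_to_indices",
    "indices_to_coords",
    "in_bounds",
    "resample_to_voxel_size",
]


@dataclass
class VoxelGrid:
    """A 3-D scalar field with physical placement.

    Parameters
    ----------
    values
        3-D array indexed ``(i, j, k)`` ~ ``(z, y, x)``.
    origin
        ``(origin_x, origin_y, origin_z)`` in Å — the corner of voxel (0,0,0).
    voxel
        ``(voxel_x, voxel_y, voxel_z)`` edge lengths in Å/voxel, all > 0.
    """

    values: np.ndarray
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    voxel: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise InvalidParameterError(
                f"grid values must be 3-D, got ndim={self.values.ndim}"
            )
        self.origin = tuple(float(c) for c in self.origin)
        self.voxel = tuple(float(v) for v in self.voxel)
        if len(self.origin) != 3 or len(self.voxel) != 3:
            raise InvalidParameterError("origin and voxel must have 3 components")
        if any(not math.isfinite(c) for c in self.origin):
            raise InvalidParameterError(f"non-finite origin {self.origin}")
        if any((not math.isfinite(v)) or v <= 0 for v in self.voxel):
            raise InvalidParameterError(f"voxel sizes must be > 0, got {self.voxel}")
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("grid values contain non-finite entries")

    # -- geometry helpers ---------------------------------------------------

    @property
    def dims(self) -> tuple[int, int, int]:
        """(n_i, n_j, n_k) — sections, rows, columns."""
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_zyx(self) -> np.ndarray:
        vx, vy, vz = self.voxel
        return np.array([vz, vy, vx])

    @property
    def origin_zyx(self) -> np.ndarray:
        ox, oy, oz = self.origin
        return np.array([oz, oy, ox])

    @property
    def extent(self) -> tuple[tuple[float, float], ...]:
        """Physical half-open interval per axis in (x, y, z) order."""
        n_i, n_j, n_k = self.dims
        n_xyz = (n_k, n_j, n_i)
        return tuple(
            (o, o + n * v) for o, v, n in zip(self.origin, self.voxel, n_xyz)
        )

    def contains_point(self, point) -> bool:
        """True iff the physical (x, y, z) point falls inside the grid extent."""
        return all(lo <= c < hi for c, (lo, hi) in zip(point, self.extent))

    def empty_like(self, dtype=np.float32) -> "VoxelGrid":
        """A zero-valued grid with identical geometry."""
        return VoxelGrid(
            np.zeros(self.dims, dtype=dtype), origin=self.origin, voxel=self.voxel
        )

    def same_geometry(self, other: "VoxelGrid", rtol: float = 1e-6) -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.origin, other.origin, rtol=rtol, atol=1e-6)
            and np.allclose(self.voxel, other.voxel, rtol=rtol, atol=1e-6)
        )


def coords_to_indices(point, grid: VoxelGrid):
    """Map a physical (x, y, z) point to its (i, j, k) grid index.

    Returns ``None`` (the out-of-bounds marker) when the floored index falls
    outside the grid; raises :class:`InvalidParameterError` on non-finite
    coordinates.
    """
    x, y, z = (float(c) for c in point)
    if not all(math.isfinite(c) for c in (x, y, z)):
        raise InvalidParameterError(f"non-finite coordinates {(x, y, z)}")
    ox, oy, oz = grid.origin
    vx, vy, vz = grid.voxel
    idx = (
        math.floor((z - oz) / vz),
        math.floor((y - oy) / vy),
        math.floor((x - ox) / vx),
    )
    return idx if in_bounds(idx, grid) else None


def floor_indices(points: np.ndarray, grid: VoxelGrid):
    """Vectorized floor transform for an (N, 3) array of (x, y, z) points.

    Returns ``(indices, valid)`` where ``indices`` is (N, 3) int64 in
    (i, j, k) order and ``valid`` marks rows that are in bounds.
    """
    pts = np.asarray(points, dtype=float)
    if not np.all(np.isfinite(pts)):
        raise InvalidParameterError("non-finite coordinates in point array")
    rel = (pts[:, ::-1] - grid.origin_zyx) / grid.voxel_zyx  # (z, y, x) order
    idx = np.floor(rel).astype(np.int64)
    dims = np.asarray(grid.dims)
    valid = np.all((idx >= 0) & (idx < dims), axis=1)
    return idx, valid


def indices_to_coords(idx, grid: VoxelGrid) -> tuple[float, float, float]:
    """Physical (x, y, z) center of voxel (i, j, k); raises out of bounds."""
    if not in_bounds(idx, grid):
        raise GridBoundsError(f"index {tuple(idx)} outside dims {grid.dims}")
    i, j, k = (int(c) for c in idx)
    ox, oy, oz = grid.origin
    vx, vy, vz = grid.voxel
    return (ox + (k + 0.5) * vx, oy + (j + 0.5) * vy, oz + (i + 0.5) * vz)


def in_bounds(idx, grid: VoxelGrid) -> bool:
    """True iff 0 <= component < dim for all three components of (i, j, k)."""
    try:
        i, j, k = (int(c) for c in idx)
    except (TypeError, ValueError):
        return False
    n_i, n_j, n_k = grid.dims
    return 0 <= i < n_i and 0 <= j < n_j and 0 <= k < n_k


def resample_to_voxel_size(grid: VoxelGrid, target: float = 1.0) -> VoxelGrid:
    """Trilinearly resample a grid onto an isotropic ``target`` Å voxel.

    The output keeps the input origin; dimensions cover the input physical
    extent (``ceil(extent / target)`` per axis); values are interpolated at
    output voxel centers, zero-filled outside the input extent.
    """
    if not (target > 0) or not math.isfinite(target):
        raise InvalidParameterError(f"target voxel size must be > 0, got {target}")
    n_zyx = np.asarray(grid.dims, dtype=float)
    extent_zyx = n_zyx * grid.voxel_zyx
    new_dims = tuple(int(math.ceil(e / target - 1e-9)) for e in extent_zyx)
    # fractional input index of each output voxel center, per axis
    axes = [
        ((np.arange(n) + 0.5) * target) / v - 0.5
        for n, v in zip(new_dims, grid.voxel_zyx)
    ]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    vals = ndimage.map_coordinates(
        np.asarray(grid.values, dtype=np.float64),
        [zz, yy, xx],
        order=1,
        mode="constant",
        cval=0.0,
        prefilter=False,
    )
    return VoxelGrid(
        vals.astype(np.float32),
        origin=grid.origin,
        voxel=(target, target, target),
    )
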