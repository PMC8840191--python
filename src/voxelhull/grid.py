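"""Axis-aligned voxel grids: construction, refitting, surface extraction.

The grid stores occupancy as a boolean array of shape ``(nx, ny, nz)`` whose
axes map to world x/y/z.  The center of voxel ``(i, j, k)`` is
``origin + ((i, j, k) + 0.5) * voxel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import EmptyReconstructionError
from .geometry import Aabb

__all__ = [
    "VoxelGrid",
    "make_grid",
    "make_grid_on_lattice",
    "occupied_bounding_box",
    "surface_voxels",
]


@dataclass
class VoxelGrid:
    origin: np.ndarray
    voxel_size: float
    occupancy: np.ndarray
    votes: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be positive")
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.ndim != 3 or min(self.occupancy.shape) < 1:
            raise ValueError("occupancy must be a non-empty 3D array")
        if self.votes is not None and self.votes.shape != self.occupancy.shape:
            raise ValueError("votes array shape must match occupancy")

    @property
    def dims(self) -> tuple:
        return self.occupancy.shape

    @property
    def extent_box(self) -> Aabb:
        hi = self.origin + np.array(self.dims) * self.voxel_size
        return Aabb(self.origin, hi)

    def centers(self, indices: Optional[np.ndarray] = None) -> np.ndarray:
        """World-space centers of the given (n, 3) voxel indices (all if None)."""
        if indices is None:
            nx, ny, nz = self.dims
            ii, jj, kk = np.meshgrid(
                np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
            )
            indices = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
        return self.origin + (np.asarray(indices, dtype=float) + 0.5) * self.voxel_size

    def occupied_indices(self) -> np.ndarray:
        return np.argwhere(self.occupancy)

    def occupied_centers(self) -> np.ndarray:
        return self.centers(self.occupied_indices())

    def n_occupied(self) -> int:
        return int(self.occupancy.sum())


def make_grid(box: Aabb, voxel_size: float) -> VoxelGrid:
    """Build an empty grid fully covering ``box`` with cubic voxels.

    Dims are rounded up (``ceil(extent / D)``) so the requested box is never
    truncated; the grid may overhang on the max side.
    """
    if voxel_size <= 0:
        raise ValueError("voxel size must be positive")
    extent = box.extent
    if np.any(extent <= 0):
        raise ValueError("box must be non-degenerate in every axis")
    dims = np.ceil(extent / voxel_size - 1e-9).astype(int)
    dims = np.maximum(dims, 1)
    occ = np.zeros(tuple(dims), dtype=bool)
    return VoxelGrid(box.min_corner.copy(), float(voxel_size), occ)


def make_grid_on_lattice(box: Aabb, voxel_size: float, anchor: np.ndarray) -> VoxelGrid:
    """Build an empty grid covering ``box`` whose lattice is anchored at ``anchor``.

    The grid origin is ``anchor + i0 * D`` for integer ``i0``, so voxel
    centers of every grid built from the same anchor coincide where they
    overlap.  Used to make per-segment grids set-union compatible.
    """
    if voxel_size <= 0:
        raise ValueError("voxel size must be positive")
    anchor = np.asarray(anchor, dtype=float).reshape(3)
    lo_idx = np.floor((box.min_corner - anchor) / voxel_size + 1e-9).astype(int)
    hi_idx = np.ceil((box.max_corner - anchor) / voxel_size - 1e-9).astype(int)
    dims = np.maximum(hi_idx - lo_idx, 1)
    origin = anchor + lo_idx * voxel_size
    return VoxelGrid(origin, float(voxel_size), np.zeros(tuple(dims), dtype=bool))


def occupied_bounding_box(grid: VoxelGrid, margin_voxels: int = 0) -> Aabb:
    """Tight box over occupied voxel cubes, grown by ``margin_voxels * D``.

    The result is clipped to the grid extent, so the margin never reaches
    outside the original volume.
    """
    idx = grid.occupied_indices()
    if idx.shape[0] == 0:
        raise EmptyReconstructionError("grid has no occupied voxels")
    lo_idx = np.clip(idx.min(axis=0) - margin_voxels, 0, None)
    hi_idx = np.clip(idx.max(axis=0) + 1 + margin_voxels, None, np.array(grid.dims))
    lo = grid.origin + lo_idx * grid.voxel_size
    hi = grid.origin + hi_idx * grid.voxel_size
    return Aabb(lo, hi)


def surface_voxels(grid: VoxelGrid, connectivity: int = 6) -> np.ndarray:
    """Indices (n, 3) of occupied voxels removed by one morphological erosion.

    ``connectivity`` selects the structuring element: 6 (faces, default) or
    26 (full cube).  Out-of-grid neighbors count as empty, so the grid
    boundary is always surface.
    """
    if connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    elif connectivity == 26:
        structure = ndimage.generate_binary_structure(3, 3)
    else:
        raise ValueError("connectivity must be 6 or 26")
    occ = grid.occupancy
    eroded = ndimage.binary_erosion(occ, structure=structure, border_value=0)
    return np.argwhere(occ & ~eroded)
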