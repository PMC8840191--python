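"""Reconstruction quality metrics against a reference surface point cloud.

Two complementary metrics:

* **Erroneous voxels** — reconstructed voxels lying outside the reference
  surface, detected by a negative dot product between the vector from the
  voxel center to its nearest reference point and that point's outward
  normal.  Voxels closer than one voxel size to the reference are exempt.
  Evaluated over all occupied voxels by default.
* **P2S distances** — Euclidean distance from each *surface* voxel center
  (erosion shell) to the nearest reference point, summarized by their RMS
  and a 1 mm histogram (40 bins + overflow at 40 mm).

Nearest-neighbor queries use an exact KD-tree so results are bit-stable
against brute-force oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .errors import InvalidReferenceError

__all__ = [
    "ReferenceSurface",
    "ErroneousVoxelRecords",
    "MetricsReport",
    "erroneous_voxels",
    "p2s_distances",
    "rms",
    "p2s_histogram",
    "estimate_normals",
    "evaluate_reconstruction",
]

HISTOGRAM_BINS = 41  # 1 mm bins covering 0..40 mm plus one overflow bin


@dataclass
class ReferenceSurface:
    """Point cloud with outward unit normals."""

    points: np.ndarray
    normals: np.ndarray
    degenerate: Optional[np.ndarray] = None  # normals from collinear neighborhoods

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.normals is None:
            raise InvalidReferenceError("reference surface requires normals")
        self.normals = np.atleast_2d(np.asarray(self.normals, dtype=float))
        if self.points.shape[0] < 1:
            raise InvalidReferenceError("reference surface must have at least one point")
        if self.points.shape != self.normals.shape:
            raise InvalidReferenceError("points and normals must have equal shape")
        norms = np.linalg.norm(self.normals, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise InvalidReferenceError("normals must be unit length (tol 1e-6)")

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class ErroneousVoxelRecords:
    """Vectorized per-voxel diagnostics of the erroneous-voxel test."""

    nearest_index: np.ndarray   # index of the nearest reference point
    dot: np.ndarray             # signed A = (nearest - center) . normal, meters
    distance: np.ndarray        # center-to-nearest Euclidean distance, meters
    erroneous: np.ndarray       # (A < 0) and (distance >= voxel size)


@dataclass
class MetricsReport:
    erroneous_count: int
    p2s: np.ndarray
    rms: float
    histogram: np.ndarray
    voxel_size: float
    n_occupied: int
    n_surface: int

    def to_dict(self) -> dict:
        return {
            "erroneous_count": int(self.erroneous_count),
            "rms_m": float(self.rms),
            "rms_mm": float(self.rms * 1000.0),
            "histogram": [int(c) for c in self.histogram],
            "voxel_size_m": float(self.voxel_size),
            "n_occupied": int(self.n_occupied),
            "n_surface": int(self.n_surface),
            "p2s_mean_mm": float(np.mean(self.p2s) * 1000.0) if len(self.p2s) else 0.0,
        }


def erroneous_voxels(centers: np.ndarray, reference: ReferenceSurface, voxel_size: float):
    """Count voxels outside the reference surface; returns ``(count, records)``.

    A voxel is erroneous iff the dot product of (nearest reference point -
    voxel center) with the reference point's outward normal is negative and
    the voxel lies at least one voxel size away from that point.
    """
    if voxel_size <= 0:
        raise ValueError("voxel size must be positive")
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if centers.shape[0] == 0:
        empty = np.zeros(0)
        return 0, ErroneousVoxelRecords(empty.astype(int), empty, empty, empty.astype(bool))
    tree = cKDTree(reference.points)
    dist, idx = tree.query(centers, k=1)
    vec = reference.points[idx] - centers
    dot = np.einsum("ij,ij->i", vec, reference.normals[idx])
    bad = (dot < 0) & (dist >= voxel_size)
    records = ErroneousVoxelRecords(idx, dot, dist, bad)
    return int(bad.sum()), records


def p2s_distances(centers: np.ndarray, reference: ReferenceSurface) -> np.ndarray:
    """Exact nearest-neighbor distance of each voxel center to the reference."""
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if centers.shape[0] == 0:
        return np.zeros(0)
    tree = cKDTree(reference.points)
    dist, _ = tree.query(centers, k=1)
    return dist


def rms(distances: np.ndarray) -> float:
    """Root-mean-square of the given distances."""
    d = np.asarray(distances, dtype=float).ravel()
    if d.size == 0:
        raise ValueError("rms of an empty distance list is undefined")
    return float(np.sqrt(np.mean(d * d)))


def p2s_histogram(distances: np.ndarray) -> np.ndarray:
    """41-bin histogram: 1 mm bins [k, k+1) mm for k=0..39, then >= 40 mm."""
    d = np.asarray(distances, dtype=float).ravel()
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    mm = d * 1000.0
    counts = np.zeros(HISTOGRAM_BINS, dtype=np.int64)
    bins = np.floor(mm).astype(np.int64)
    bins = np.clip(bins, 0, HISTOGRAM_BINS - 1)
    np.add.at(counts, bins, 1)
    return counts


def estimate_normals(points: np.ndarray, k: int, interior_hint: np.ndarray) -> ReferenceSurface:
    """PCA normals for a cloud lacking them, oriented away from an interior point.

    The normal of each point is the smallest-eigenvalue eigenvector of its
    k-nearest-neighbor covariance.  Neighborhoods whose two smallest
    covariance eigenvalues are both (near) zero are collinear; their normals
    are flagged in ``ReferenceSurface.degenerate``.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if k < 3:
        raise ValueError("k must be at least 3")
    if points.shape[0] <= k:
        raise ValueError("need more points than neighbors")
    hint = np.asarray(interior_hint, dtype=float).reshape(3)
    tree = cKDTree(points)
    _, nbr = tree.query(points, k=k)
    neigh = points[nbr]  # (n, k, 3)
    centered = neigh - neigh.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered) / k
    w, v = np.linalg.eigh(cov)
    normals = v[:, :, 0]
    degenerate = w[:, 1] <= 1e-12 * np.maximum(w[:, 2], 1e-300)
    flip = np.einsum("ij,ij->i", normals, points - hint) < 0
    normals = np.where(flip[:, None], -normals, normals)
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return ReferenceSurface(points=points, normals=normals, degenerate=degenerate)


def evaluate_reconstruction(grid, reference: ReferenceSurface,
                            connectivity: int = 6,
                            erroneous_scope: str = "occupied") -> MetricsReport:
    """All metrics for one reconstruction: erroneous count, P2S, RMS, histogram.

    ``erroneous_scope`` selects whether the erroneous-voxel test runs over
    every occupied voxel (default) or the erosion surface shell only.
    """
    from .grid import surface_voxels  # local import to avoid a cycle

    if erroneous_scope not in ("occupied", "surface"):
        raise ValueError("erroneous_scope must be 'occupied' or 'surface'")
    surf_idx = surface_voxels(grid, connectivity=connectivity)
    surf_centers = grid.centers(surf_idx) if surf_idx.shape[0] else np.zeros((0, 3))
    if erroneous_scope == "occupied":
        err_centers = grid.occupied_centers()
    else:
        err_centers = surf_centers
    count, _ = erroneous_voxels(err_centers, reference, grid.voxel_size)
    dists = p2s_distances(surf_centers, reference)
    return MetricsReport(
        erroneous_count=count,
        p2s=dists,
        rms=rms(dists) if dists.size else 0.0,
        histogram=p2s_histogram(dists),
        voxel_size=grid.voxel_size,
        n_occupied=grid.n_occupied(),
        n_surface=int(surf_idx.shape[0]),
    )
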