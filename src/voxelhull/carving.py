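"""Whole-body silhouette carving: probability voting and threshold occupancy.

Each voxel center is projected into every view; the silhouette intensity at
the hit pixel, normalized to [0, 1], is accumulated as that view's vote.
A voxel is kept iff its vote sum reaches a fraction ``T`` of the
participating views.  Votes are accumulated view-by-view in list order so
results are bit-identical to a scalar reference loop.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .errors import EmptyReconstructionError, InputMismatchError
from .geometry import CameraModel, project_points, rig_bounding_box
from .grid import VoxelGrid, make_grid, occupied_bounding_box

__all__ = [
    "ProbabilitySilhouette",
    "CarveConfig",
    "accumulate_votes",
    "carve",
    "reconstruct_coarse_to_fine",
]


@dataclass(frozen=True)
class ProbabilitySilhouette:
    """8-bit per-pixel silhouette confidence, 0 (background) to 255 (subject)."""

    values: np.ndarray
    camera_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("silhouette must be a 2D array")
        if v.dtype != np.uint8:
            if np.issubdtype(v.dtype, np.integer) and v.min() >= 0 and v.max() <= 255:
                v = v.astype(np.uint8)
            else:
                raise ValueError("silhouette values must be uint8 (0..255)")
        v = v.copy()
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def height(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class CarveConfig:
    """Carving parameters.

    threshold
        Vote threshold as a fraction ``T`` of participating views.
    d0, d1
        Coarse and fine voxel sizes in meters (``d1 <= d0``).
    out_of_frame
        "background": projections outside the image (or behind the camera)
        contribute a zero vote while the view still counts.
        "exclude": such views are dropped from that voxel's denominator.
    interpolation
        "nearest" (floor pixel lookup, default) or "bilinear".
    refit_margin_voxels
        Coarse voxels of padding added around the occupied coarse box
        before fine carving.
    """

    threshold: float = 0.95
    d0: float = 0.064
    d1: float = 0.004
    out_of_frame: str = "background"
    interpolation: str = "nearest"
    refit_margin_voxels: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError("threshold must be in [0, 1]")
        if self.d0 <= 0 or self.d1 <= 0 or self.d1 > self.d0:
            raise ValueError("voxel sizes must satisfy 0 < d1 <= d0")
        if self.out_of_frame not in ("background", "exclude"):
            raise ValueError("out_of_frame must be 'background' or 'exclude'")
        if self.interpolation not in ("nearest", "bilinear"):
            raise ValueError("interpolation must be 'nearest' or 'bilinear'")


def _check_inputs(cameras, silhouettes) -> None:
    if len(cameras) == 0:
        raise InputMismatchError("at least one camera/silhouette pair required")
    if len(cameras) != len(silhouettes):
        raise InputMismatchError(
            f"{len(cameras)} cameras but {len(silhouettes)} silhouettes"
        )
    for cam, sil in zip(cameras, silhouettes):
        if (sil.height, sil.width) != (cam.height, cam.width):
            raise InputMismatchError(
                f"silhouette size {sil.width}x{sil.height} does not match camera "
                f"'{cam.camera_id}' ({cam.width}x{cam.height})"
            )


def _view_votes(camera: CameraModel, sil: ProbabilitySilhouette, centers: np.ndarray,
                interpolation: str):
    """Per-voxel normalized vote of one view, plus its participation mask."""
    uv, in_front = project_points(camera, centers)
    img = sil.values
    h, w = img.shape
    vals = np.zeros(centers.shape[0])
    if interpolation == "nearest":
        with np.errstate(invalid="ignore"):
            iu = np.floor(uv[:, 0]).astype(np.int64, copy=False)
            iv = np.floor(uv[:, 1]).astype(np.int64, copy=False)
        valid = in_front & (uv[:, 0] >= 0) & (uv[:, 0] < w) & (uv[:, 1] >= 0) & (uv[:, 1] < h)
        vals[valid] = img[iv[valid], iu[valid]] / 255.0
    else:  # bilinear between pixel centers, clamped at borders
        valid = in_front & (uv[:, 0] >= 0) & (uv[:, 0] < w) & (uv[:, 1] >= 0) & (uv[:, 1] < h)
        x = np.clip(uv[valid, 0] - 0.5, 0, w - 1)
        y = np.clip(uv[valid, 1] - 0.5, 0, h - 1)
        x0 = np.floor(x).astype(np.int64)
        y0 = np.floor(y).astype(np.int64)
        x1 = np.minimum(x0 + 1, w - 1)
        y1 = np.minimum(y0 + 1, h - 1)
        fx = x - x0
        fy = y - y0
        top = img[y0, x0] * (1 - fx) + img[y0, x1] * fx
        bot = img[y1, x0] * (1 - fx) + img[y1, x1] * fx
        vals[valid] = (top * (1 - fy) + bot * fy) / 255.0
    return vals, valid


def accumulate_votes(
    grid: VoxelGrid,
    cameras: Sequence[CameraModel],
    silhouettes: Sequence[ProbabilitySilhouette],
    config: Optional[CarveConfig] = None,
) -> VoxelGrid:
    """Fill ``grid.votes`` with the per-voxel sum of normalized silhouette votes."""
    config = config or CarveConfig()
    votes, _ = _votes_and_counts(grid, cameras, silhouettes, config)
    grid.votes = votes.reshape(grid.dims)
    return grid

def _votes_and_counts(grid, cameras, silhouettes, config):
    _check_inputs(cameras, silhouettes)
    centers = grid.centers()
    votes = np.zeros(centers.shape[0])
    counts = np.zeros(centers.shape[0], dtype=np.int64)
    for cam, sil in zip(cameras, silhouettes):
        vals, valid = _view_votes(cam, sil, centers, config.interpolation)
        votes += vals
        counts += valid
    return votes, counts


def carve(
    grid: VoxelGrid,
    cameras: Sequence[CameraModel],
    silhouettes: Sequence[ProbabilitySilhouette],
    config: CarveConfig,
) -> VoxelGrid:
    """Fill ``grid.occupancy``: voxel kept iff ``votes >= T * n_views``.

    Under the "exclude" out-of-frame policy the denominator is the number of
    views that actually saw the voxel; voxels seen by no view are dropped.
    """
    votes, counts = _votes_and_counts(grid, cameras, silhouettes, config)
    if config.out_of_frame == "background":
        occ = votes >= config.threshold * len(cameras)
    else:
        occ = (counts > 0) & (votes >= config.threshold * counts)
    grid.votes = votes.reshape(grid.dims)
    grid.occupancy = occ.reshape(grid.dims)
    return grid


def reconstruct_coarse_to_fine(
    cameras: Sequence[CameraModel],
    silhouettes: Sequence[ProbabilitySilhouette],
    config: CarveConfig,
) -> VoxelGrid:
    """Two-stage carve: coarse over the rig bounding box, fine in the refit box.

    A coarse carve at ``d0`` over the camera-center bounding box locates the
    subject; the occupied box (plus margin) is then carved at ``d1``.
    Raises :class:`EmptyReconstructionError` if the coarse stage keeps
    nothing.
    """
    coarse_box = rig_bounding_box(cameras)
    coarse = carve(make_grid(coarse_box, config.d0), cameras, silhouettes, config)
    if coarse.n_occupied() == 0:
        raise EmptyReconstructionError("coarse carve produced no occupied voxels")
    fine_box = occupied_bounding_box(coarse, margin_voxels=config.refit_margin_voxels)
    fine = carve(make_grid(fine_box, config.d1), cameras, silhouettes, config)
    return fine
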