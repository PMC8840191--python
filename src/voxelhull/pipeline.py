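"""Segmented carving pipeline: conventional hull -> skeleton -> per-bone
segments -> segment-masked silhouettes -> per-segment carving -> merged model.

All per-segment grids are snapped to the lattice of the conventional fine
grid, so the final merge is an exact voxel-set union.  Segments that fail
(no voxels, no usable views) degrade to warnings rather than aborting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .carving import CarveConfig, ProbabilitySilhouette, carve, reconstruct_coarse_to_fine
from .errors import AlignmentError, EmptyProjectionError
from .geometry import Aabb, CameraModel
from .grid import VoxelGrid, make_grid_on_lattice
from .segmentation import (
    SegmentationConfig,
    SegmentViewQuality,
    Skeleton,
    assign_to_bones,
    render_segment_mask,
    segment_silhouette,
    select_views,
    triangulate_skeleton,
    uncertain_ratio,
)

log = logging.getLogger(__name__)

__all__ = [
    "SsfsConfig",
    "SsfsResult",
    "segment_volume",
    "reconstruct_segment",
    "merge_segments",
    "run_ssfs",
]


@dataclass(frozen=True)
class SsfsConfig:
    """Configuration of the segmented pipeline.

    ``segment_margin_voxels`` is expressed in units of the *coarse* voxel
    size ``carve.d0`` and pads each segment's bounding box before fine
    carving, so silhouette-noise erosion of the conventional hull cannot
    clip a segment.
    """

    carve: CarveConfig = field(default_factory=CarveConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    bones: Optional[Sequence[Tuple[str, str]]] = None  # None -> default topology
    segment_margin_voxels: int = 1


@dataclass
class SsfsResult:
    """Output of :func:`run_ssfs`.

    ``grid`` is the merged model; ``conventional`` the whole-body carve the
    segmentation was derived from (useful as a baseline).  Per-segment
    diagnostics are keyed by bone index.
    """

    grid: VoxelGrid
    conventional: VoxelGrid
    segment_grids: Dict[int, VoxelGrid]
    qualities: Dict[int, List[SegmentViewQuality]]
    kept_views: Dict[int, List[str]]
    skeleton: Skeleton
    warnings: List[str]
    config: SsfsConfig


def segment_volume(
    centers: np.ndarray,
    labels: np.ndarray,
    segment_id: int,
    voxel_size: float,
    margin_voxels: int = 1,
) -> Optional[Aabb]:
    """Bounding box of one segment's voxel cubes, padded by ``margin_voxels * D``.

    Returns None for an empty segment (caller warns and skips).
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    sel = np.asarray(labels) == segment_id
    if not sel.any():
        return None
    pts = centers[sel]
    half = voxel_size / 2.0
    pad = margin_voxels * voxel_size
    return Aabb(pts.min(axis=0) - half - pad, pts.max(axis=0) + half + pad)


def reconstruct_segment(
    box: Aabb,
    cameras: Sequence[CameraModel],
    silhouettes: Sequence[ProbabilitySilhouette],
    config: CarveConfig,
    lattice_anchor: np.ndarray,
) -> VoxelGrid:
    """Carve one segment at ``d1`` inside its box on the shared lattice."""
    grid = make_grid_on_lattice(box, config.d1, lattice_anchor)
    return carve(grid, cameras, silhouettes, config)


def merge_segments(segment_grids: Sequence[VoxelGrid]) -> VoxelGrid:
    """Union of segment occupancies on the minimal covering grid.

    All grids must share the voxel size and snap to one lattice (origin
    offsets integer multiples of D), else :class:`AlignmentError`.
    """
    if len(segment_grids) == 0:
        raise ValueError("nothing to merge")
    d = segment_grids[0].voxel_size
    anchor = segment_grids[0].origin
    offsets = []
    for g in segment_grids:
        if abs(g.voxel_size - d) > 1e-12 * max(d, 1.0):
            raise AlignmentError("segment grids have different voxel sizes")
        off = (g.origin - anchor) / d
        off_int = np.rint(off)
        if np.any(np.abs(off - off_int) > 1e-6):
            raise AlignmentError("segment grid lattices are misaligned")
        offsets.append(off_int.astype(np.int64))
    lo = np.min([o for o in offsets], axis=0)
    hi = np.max([o + np.array(g.dims) for o, g in zip(offsets, segment_grids)], axis=0)
    dims = hi - lo
    occ = np.zeros(tuple(dims), dtype=bool)
    for o, g in zip(offsets, segment_grids):
        s = o - lo
        occ[s[0] : s[0] + g.dims[0], s[1] : s[1] + g.dims[1], s[2] : s[2] + g.dims[2]] |= g.occupancy
    return VoxelGrid(anchor + lo * d, d, occ)


def run_ssfs(
    cameras: Sequence[CameraModel],
    silhouettes: Sequence[ProbabilitySilhouette],
    detections: Dict[str, Dict[str, Sequence[float]]],
    config: Optional[SsfsConfig] = None,
) -> SsfsResult:
    """Run the full segmented pipeline; deterministic for fixed inputs.

    Steps: conventional coarse-to-fine carve (all views, no filtering) ->
    skeleton triangulation -> per-voxel bone labels -> per-segment masks,
    segmented silhouettes and uncertain-ratio view selection -> per-segment
    carving on the shared lattice -> set-union merge.
    """
    config = config or SsfsConfig()
    warn_log: List[str] = []

    conventional = reconstruct_coarse_to_fine(cameras, silhouettes, config.carve)
    skeleton = triangulate_skeleton(detections, cameras, bones=config.bones)
    centers = conventional.occupied_centers()
    labels = assign_to_bones(centers, skeleton)

    d1 = config.carve.d1
    margin_m_voxels = max(
        1, int(round(config.segment_margin_voxels * config.carve.d0 / d1))
    )
    seg_grids: Dict[int, VoxelGrid] = {}
    qualities: Dict[int, List[SegmentViewQuality]] = {}
    kept_views: Dict[int, List[str]] = {}
    cam_by_id = {c.camera_id: c for c in cameras}

    for seg_id in range(len(skeleton.bones)):
        box = segment_volume(centers, labels, seg_id, d1, margin_voxels=margin_m_voxels)
        if box is None:
            msg = f"segment {seg_id} {skeleton.bones[seg_id]}: no voxels; skipped"
            warn_log.append(msg)
            log.warning(msg)
            continue
        seg_centers = centers[labels == seg_id]
        seg_quals: List[SegmentViewQuality] = []
        seg_sils: Dict[str, ProbabilitySilhouette] = {}
        for cam, sil in zip(cameras, silhouettes):
            mask = render_segment_mask(
                seg_centers, d1, cam, config.segmentation.dilation_radius
            )
            seg_sil = segment_silhouette(sil, mask)
            try:
                q = uncertain_ratio(seg_sil, mask, segment_id=seg_id, camera_id=cam.camera_id)
            except EmptyProjectionError:
                continue  # view unusable for this segment
            seg_quals.append(q)
            seg_sils[cam.camera_id] = seg_sil
        qualities[seg_id] = seg_quals
        if not seg_quals:
            msg = f"segment {seg_id}: visible in no view; skipped"
            warn_log.append(msg)
            log.warning(msg)
            continue
        kept = select_views(seg_quals, config.segmentation)
        kept_views[seg_id] = kept
        log.info(
            "segment %d %s: F=%s kept=%s",
            seg_id,
            skeleton.bones[seg_id],
            {q.camera_id: round(q.f, 4) for q in seg_quals},
            kept,
        )
        if not kept:
            msg = f"segment {seg_id}: no views kept; skipped"
            warn_log.append(msg)
            log.warning(msg)
            continue
        seg_grid = reconstruct_segment(
            box,
            [cam_by_id[cid] for cid in kept],
            [seg_sils[cid] for cid in kept],
            config.carve,
            lattice_anchor=conventional.origin,
        )
        if seg_grid.n_occupied() == 0:
            msg = f"segment {seg_id}: empty reconstruction"
            warn_log.append(msg)
            log.warning(msg)
        seg_grids[seg_id] = seg_grid

    if not seg_grids:
        raise AlignmentError("no segment produced a grid; nothing to merge")
    merged = merge_segments(list(seg_grids.values()))
    return SsfsResult(
        grid=merged,
        conventional=conventional,
        segment_grids=seg_grids,
        qualities=qualities,
        kept_views=kept_views,
        skeleton=skeleton,
        warnings=warn_log,
        config=config,
    )
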