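"""Body segmentation: skeleton triangulation, bone labeling, segment masks,
and the uncertain-pixel view filter.

A "bone" is the 3D segment between two named joints.  Voxels are labeled by
their nearest bone; the per-bone voxel sets are projected back into each
view to build binary segment masks, which gate the silhouettes.  A view is
rejected for a segment when its uncertain-pixel ratio
``F = M / N`` (uncertain silhouette pixels over segment-projection pixels)
exceeds a threshold.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .carving import ProbabilitySilhouette
from .errors import EmptyProjectionError, IncompleteSkeletonError, InputMismatchError
from .geometry import CameraModel, pixel_ray, project_points, triangulate_rays

log = logging.getLogger(__name__)

__all__ = [
    "Skeleton",
    "SegmentViewQuality",
    "SegmentationConfig",
    "DEFAULT_JOINTS",
    "DEFAULT_BONES",
    "triangulate_skeleton",
    "assign_to_bones",
    "point_segment_distances",
    "render_segment_mask",
    "segment_silhouette",
    "uncertain_ratio",
    "select_views",
]

# Default 15-joint / 14-bone topology.  The joint set is configurable; this
# one covers head, arms, spine and legs.
DEFAULT_JOINTS = [
    "head", "neck",
    "l_shoulder", "l_elbow", "l_wrist",
    "r_shoulder", "r_elbow", "r_wrist",
    "pelvis",
    "l_hip", "l_knee", "l_ankle",
    "r_hip", "r_knee", "r_ankle",
]

DEFAULT_BONES: List[Tuple[str, str]] = [
    ("head", "neck"),
    ("neck", "l_shoulder"),
    ("l_shoulder", "l_elbow"),
    ("l_elbow", "l_wrist"),
    ("neck", "r_shoulder"),
    ("r_shoulder", "r_elbow"),
    ("r_elbow", "r_wrist"),
    ("pelvis", "neck"),
    ("pelvis", "l_hip"),
    ("l_hip", "l_knee"),
    ("l_knee", "l_ankle"),
    ("pelvis", "r_hip"),
    ("r_hip", "r_knee"),
    ("r_knee", "r_ankle"),
]


@dataclass
class Skeleton:
    """Named 3D joints plus an ordered bone list (pairs of joint names)."""

    joints: Dict[str, np.ndarray]
    bones: List[Tuple[str, str]]

    def __post_init__(self) -> None:
        self.joints = {k: np.asarray(v, dtype=float).reshape(3) for k, v in self.joints.items()}
        self.bones = [tuple(b) for b in self.bones]
        if not self.bones:
            raise ValueError("bone list must be non-empty")
        for a, b in self.bones:
            if a == b:
                raise ValueError(f"bone endpoints must be distinct names: {a!r}")
            if a not in self.joints or b not in self.joints:
                raise ValueError(f"bone ({a}, {b}) references unknown joints")

    def bone_endpoints(self) -> Tuple[np.ndarray, np.ndarray]:
        """(n_bones, 3) arrays of bone start and end positions."""
        a = np.array([self.joints[x] for x, _ in self.bones])
        b = np.array([self.joints[y] for _, y in self.bones])
        return a, b


@dataclass(frozen=True)
class SegmentViewQuality:
    """Eq-style uncertain-pixel statistics of one segment in one view."""

    segment_id: int
    camera_id: str
    m: int  # silhouette pixels with value in [1, 254] inside the mask
    n: int  # mask pixels with value 255
    f: float  # m / n


@dataclass(frozen=True)
class SegmentationConfig:
    """View-filter and mask parameters.

    f_t
        Reject a view for a segment when its uncertain ratio F exceeds this.
    dilation_radius
        Disk radius (pixels) stamped around each projected voxel center;
        None selects the per-voxel projected half-diagonal automatically,
        0 reproduces bare single-pixel dots.
    min_views
        If fewer views survive the F filter, the lowest-F views are kept up
        to this count (with a warning).
    """

    f_t: float = 0.1
    dilation_radius: Optional[int] = None
    min_views: int = 3

    def __post_init__(self) -> None:
        if self.f_t < 0:
            raise ValueError("f_t must be non-negative")
        if self.dilation_radius is not None and self.dilation_radius < 0:
            raise ValueError("dilation radius must be non-negative")
        if self.min_views < 0:
            raise ValueError("min_views must be non-negative")


def triangulate_skeleton(
    detections: Dict[str, Dict[str, Sequence[float]]],
    cameras: Sequence[CameraModel],
    bones: Optional[Sequence[Tuple[str, str]]] = None,
    min_views: int = 2,
) -> Skeleton:
    """Triangulate 2D joint detections into a 3D skeleton.

    ``detections`` maps camera id -> {joint name -> (u, v)}.  Each joint is
    triangulated from the rays of all views that detected it; joints seen in
    fewer than ``min_views`` views are absent from the result.

    Raises
    ------
    IncompleteSkeletonError
        If any bone endpoint could not be triangulated.
    """
    bones = list(bones) if bones is not None else list(DEFAULT_BONES)
    cam_by_id = {c.camera_id: c for c in cameras}
    joint_names: List[str] = []
    for per_cam in detections.values():
        for name in per_cam:
            if name not in joint_names:
                joint_names.append(name)
    joints: Dict[str, np.ndarray] = {}
    for name in joint_names:
        rays = []
        for cam_id, per_cam in detections.items():
            if name in per_cam and cam_id in cam_by_id:
                rays.append(pixel_ray(cam_by_id[cam_id], per_cam[name]))
        if len(rays) >= min_views:
            joints[name] = triangulate_rays(rays)
    needed = {j for bone in bones for j in bone}
    missing = sorted(needed - set(joints))
    if missing:
        raise IncompleteSkeletonError(missing)
    return Skeleton(joints=joints, bones=bones)


def point_segment_distances(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distances (n_points, n_segments) from points to 3D segments a->b."""
    p = np.asarray(points, dtype=float)[:, None, :]  # (n, 1, 3)
    a = np.asarray(a, dtype=float)[None, :, :]       # (1, m, 3)
    u = np.asarray(b, dtype=float)[None, :, :] - a
    uu = np.einsum("nmk,nmk->nm", u, u)
    w = p - a
    t = np.einsum("nmk,nmk->nm", w, u)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(uu > 0, t / uu, 0.0)
    t = np.clip(t, 0.0, 1.0)
    closest = a + t[:, :, None] * u
    return np.linalg.norm(p - closest, axis=2)


def assign_to_bones(points: np.ndarray, skeleton: Skeleton) -> np.ndarray:
    """Label each point with the index of its nearest bone (ties: lowest index)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] == 0:
        return np.zeros(0, dtype=np.int64)
    a, b = skeleton.bone_endpoints()
    # chunk to bound the (n_points x n_bones) distance table memory
    labels = np.empty(points.shape[0], dtype=np.int64)
    step = max(1, 4_000_000 // max(len(skeleton.bones), 1))
    for s in range(0, points.shape[0], step):
        d = point_segment_distances(points[s : s + step], a, b)
        labels[s : s + step] = np.argmin(d, axis=1)
    return labels


def _auto_radii(camera: CameraModel, centers: np.ndarray, voxel_size: float) -> np.ndarray:
    """Per-voxel mask radius: exact projected half-diagonal plus raster slack."""
    half = voxel_size / 2.0
    corners = np.array(
        [[sx, sy, sz] for sx in (-half, half) for sy in (-half, half) for sz in (-half, half)]
    )
    uv_c, in_front = project_points(camera, centers)
    max_d = np.zeros(centers.shape[0])
    for off in corners:
        uv_k, ok = project_points(camera, centers + off)
        d = np.linalg.norm(uv_k - uv_c, axis=1)
        d[~(ok & in_front)] = np.nan
        max_d = np.fmax(max_d, d)
    # +sqrt(2): floor rasterization can shift center and corner pixels apart
    return np.ceil(np.nan_to_num(max_d) + math.sqrt(2.0)).astype(np.int64)


def render_segment_mask(
    centers: np.ndarray,
    voxel_size: float,
    camera: CameraModel,
    dilation_radius: Optional[int] = None,
) -> np.ndarray:
    """Binary (0/255) uint8 mask of the projected voxel centers of a segment.

    Each in-frame projection stamps its pixel plus a disk of the configured
    radius.  With ``dilation_radius=None`` the radius is the projected voxel
    half-diagonal per voxel, so the disk covers the pixel hull of the voxel
    cube's corner projections.  Behind-camera voxels are skipped.
    """
    h, w = camera.height, camera.width
    mask = np.zeros((h, w), dtype=bool)
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if centers.shape[0] == 0:
        return np.zeros((h, w), dtype=np.uint8)
    uv, in_front = project_points(camera, centers)
    ok = in_front & (uv[:, 0] >= 0) & (uv[:, 0] < w) & (uv[:, 1] >= 0) & (uv[:, 1] < h)
    if not ok.any():
        return np.zeros((h, w), dtype=np.uint8)
    iu = np.floor(uv[ok, 0]).astype(np.int64)
    iv = np.floor(uv[ok, 1]).astype(np.int64)
    if dilation_radius is not None:
        radii = np.full(iu.shape[0], int(dilation_radius), dtype=np.int64)
    else:
        radii = _auto_radii(camera, centers[ok], voxel_size)
    for r in np.unique(radii):
        sel = radii == r
        hits = np.zeros((h, w), dtype=bool)
        hits[iv[sel], iu[sel]] = True
        if r == 0:
            mask |= hits
        else:
            dist = ndimage.distance_transform_edt(~hits)
            mask |= dist <= r
    return np.where(mask, np.uint8(255), np.uint8(0))


def segment_silhouette(
    silhouette: ProbabilitySilhouette, mask: np.ndarray
) -> ProbabilitySilhouette:
    """Gate a silhouette with a binary mask: value where mask==255, else 0."""
    if mask.shape != silhouette.values.shape:
        raise InputMismatchError(
            f"mask shape {mask.shape} does not match silhouette {silhouette.values.shape}"
        )
    out = np.where(mask == 255, silhouette.values, np.uint8(0))
    return ProbabilitySilhouette(out, camera_id=silhouette.camera_id)


def uncertain_ratio(
    segment_sil: ProbabilitySilhouette,
    mask: np.ndarray,
    segment_id: int = 0,
    camera_id: str = "",
) -> SegmentViewQuality:
    """Uncertain-pixel ratio ``F = M / N`` of a segmented silhouette.

    M counts segmented-silhouette pixels with value in [1, 254]; N counts
    mask pixels equal to 255.  ``N == 0`` (segment invisible in this view)
    raises :class:`EmptyProjectionError`.
    """
    if mask.shape != segment_sil.values.shape:
        raise InputMismatchError("mask and segment silhouette sizes differ")
    n = int(np.count_nonzero(mask == 255))
    if n == 0:
        raise EmptyProjectionError(
            f"segment {segment_id} projects onto no pixel in view '{camera_id}'"
        )
    v = segment_sil.values
    m = int(np.count_nonzero((v >= 1) & (v <= 254)))
    return SegmentViewQuality(segment_id=segment_id, camera_id=camera_id or segment_sil.camera_id,
                              m=m, n=n, f=m / n)


def select_views(
    qualities: Sequence[SegmentViewQuality], config: SegmentationConfig
) -> List[str]:
    """Camera ids kept for one segment: views with ``F <= F_t``.

    If fewer than ``config.min_views`` survive, the lowest-F views are kept
    up to the minimum and a warning is emitted.
    """
    kept = [q.camera_id for q in qualities if q.f <= config.f_t]
    if len(kept) < config.min_views:
        ranked = sorted(qualities, key=lambda q: (q.f, q.camera_id))
        fallback = [q.camera_id for q in ranked[: config.min_views]]
        if qualities:
            warnings.warn(
                f"segment {qualities[0].segment_id}: only {len(kept)} views passed "
                f"F_t={config.f_t}; keeping the {len(fallback)} lowest-F views",
                stacklevel=2,
            )
        kept = fallback
    return kept
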