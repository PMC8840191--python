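"""Analytically ground-truthed synthetic scenes for end-to-end testing.

Provides a circular multi-camera rig (columns of cameras around the subject
plus ceiling cameras), articulated bodies built from capsules (swept
spheres) attached to a skeleton, exact ray-traced probability silhouettes
with optional seeded edge/blob noise, noisy 2D joint projections, and
uniform-area reference surface samples with exact outward normals.

Capsules are used because their ray intersection, signed distance, and
surface sampling are all closed-form, which keeps every downstream test
backed by an independent analytic oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .carving import ProbabilitySilhouette
from .geometry import CameraModel, project_points
from .segmentation import Skeleton

__all__ = [
    "RigSpec",
    "Capsule",
    "CapsuleBody",
    "SilhouetteNoiseModel",
    "make_rig",
    "make_body",
    "render_silhouette",
    "project_joints",
    "sample_reference",
    "POSES",
]


@dataclass(frozen=True)
class RigSpec:
    """Geometry of the synthetic capture rig.

    Defaults reproduce a 34-camera setup: 15 columns of 2 cameras each at
    heights 0.5-3.0 m on a circle, plus 4 ceiling cameras at 3.5 m.
    """

    n_columns: int = 15
    cameras_per_column: int = 2
    height_range: Tuple[float, float] = (0.5, 3.0)
    column_radius: float = 3.0
    n_ceiling: int = 4
    ceiling_height: float = 3.5
    ceiling_radius: float = 0.7
    image_size: Tuple[int, int] = (512, 512)  # (width, height)
    focal: Optional[float] = None  # pixels; None -> 0.8 * width
    target: Tuple[float, float, float] = (0.0, 0.0, 1.6)

    def __post_init__(self) -> None:
        if self.n_columns < 0 or self.cameras_per_column < 0 or self.n_ceiling < 0:
            raise ValueError("camera counts must be non-negative")
        if self.total_cameras == 0:
            raise ValueError("rig must contain at least one camera")
        if self.height_range[0] > self.height_range[1]:
            raise ValueError("height range must be ordered")
        if min(self.image_size) < 1:
            raise ValueError("image size must be positive")

    @property
    def total_cameras(self) -> int:
        return self.n_columns * self.cameras_per_column + self.n_ceiling


@dataclass(frozen=True)
class Capsule:
    """Swept sphere: segment a->b with radius r (a == b gives a ball)."""

    a: np.ndarray
    b: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("capsule radius must be positive")
        object.__setattr__(self, "a", np.asarray(self.a, dtype=float).reshape(3))
        object.__setattr__(self, "b", np.asarray(self.b, dtype=float).reshape(3))


@dataclass
class CapsuleBody:
    """Union of capsules, one per skeleton bone (same ordering)."""

    capsules: List[Capsule]
    skeleton: Skeleton

    def __post_init__(self) -> None:
        if not self.capsules:
            raise ValueError("body needs at least one capsule")
        if len(self.capsules) != len(self.skeleton.bones):
            raise ValueError("one capsule per bone required")
        a, b = self.skeleton.bone_endpoints()
        for i, cap in enumerate(self.capsules):
            if not (np.allclose(cap.a, a[i]) and np.allclose(cap.b, b[i])):
                raise ValueError(f"capsule {i} endpoints must coincide with its bone's joints")

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distance to the capsule union (< 0 inside)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        best = np.full(pts.shape[0], np.inf)
        for cap in self.capsules:
            best = np.minimum(best, _capsule_signed_distance(pts, cap))
        return best

    def contains(self, points: np.ndarray) -> np.ndarray:
        return self.signed_distance(points) <= 0.0


@dataclass(frozen=True)
class SilhouetteNoiseModel:
    """Seeded degradation of a clean binary silhouette.

    edge_band
        Half-width in pixels of the soft transition band straddling the
        silhouette boundary; band pixels get values in ``value_range``.
    edge_roughness
        Std-dev of the per-pixel jitter added to the band ramp (fractional).
    blob_rate
        Expected number of uncertain blobs per image (Poisson).
    blob_size
        Mean blob radius in pixels.
    blob_placement
        "boundary" drops blobs centered on silhouette boundary pixels,
        mimicking local silhouette-estimation failures; "uniform" scatters
        them anywhere in the image.
    value_range
        Inclusive intensity range of uncertain pixels; must stay in [1, 254].
    """

    edge_band: float = 2.0
    edge_roughness: float = 0.15
    blob_rate: float = 0.0
    blob_size: float = 6.0
    blob_placement: str = "boundary"
    value_range: Tuple[int, int] = (1, 254)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.edge_band < 0 or self.blob_rate < 0 or self.blob_size < 0:
            raise ValueError("noise magnitudes must be non-negative")
        lo, hi = self.value_range
        if not (1 <= lo <= hi <= 254):
            raise ValueError("value_range must lie within [1, 254]")
        if self.blob_placement not in ("boundary", "uniform"):
            raise ValueError("blob_placement must be 'boundary' or 'uniform'")


def _look_at_rotation(position: np.ndarray, target: np.ndarray) -> np.ndarray:
    """World-to-camera rotation with +z toward target and image-up ~ world +z."""
    fwd = target - position
    nrm = np.linalg.norm(fwd)
    if nrm == 0:
        raise ValueError("camera position coincides with target")
    z = fwd / nrm
    up = np.array([0.0, 0.0, 1.0])
    x = np.cross(z, up)
    if np.linalg.norm(x) < 1e-8:  # looking straight up/down
        up = np.array([0.0, 1.0, 0.0])
        x = np.cross(z, up)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    return np.vstack([x, y, z])


def _camera_at(position, spec: RigSpec, camera_id: str) -> CameraModel:
    position = np.asarray(position, dtype=float)
    w, h = spec.image_size
    f = spec.focal if spec.focal is not None else 0.8 * w
    R = _look_at_rotation(position, np.asarray(spec.target, dtype=float))
    t = -R @ position
    return CameraModel(fx=f, fy=f, cx=w / 2.0, cy=h / 2.0, rotation=R, translation=t,
                       width=w, height=h, camera_id=camera_id)


def make_rig(spec: Optional[RigSpec] = None) -> List[CameraModel]:
    """Build the rig cameras, all oriented at the scene target."""
    spec = spec or RigSpec()
    cameras: List[CameraModel] = []
    lo, hi = spec.height_range
    for c in range(spec.n_columns):
        theta = 2.0 * math.pi * c / spec.n_columns
        xy = spec.column_radius * np.array([math.cos(theta), math.sin(theta)])
        if spec.cameras_per_column == 1:
            heights = [0.5 * (lo + hi)]
        else:
            heights = np.linspace(lo, hi, spec.cameras_per_column)
        for k, z in enumerate(heights):
            cameras.append(_camera_at([xy[0], xy[1], z], spec, f"col{c:02d}_cam{k}"))
    for k in range(spec.n_ceiling):
        theta = 2.0 * math.pi * k / max(spec.n_ceiling, 1) + math.pi / 4.0
        pos = [spec.ceiling_radius * math.cos(theta),
               spec.ceiling_radius * math.sin(theta),
               spec.ceiling_height]
        cameras.append(_camera_at(pos, spec, f"ceil{k}"))
    return cameras


def _skeleton_from_pairs(pairs: Sequence[Tuple[str, np.ndarray, str, np.ndarray]],
                         radii: Sequence[float]) -> CapsuleBody:
    joints: Dict[str, np.ndarray] = {}
    bones: List[Tuple[str, str]] = []
    capsules: List[Capsule] = []
    for (na, pa, nb, pb), r in zip(pairs, radii):
        joints.setdefault(na, np.asarray(pa, dtype=float))
        joints.setdefault(nb, np.asarray(pb, dtype=float))
        bones.append((na, nb))
        capsules.append(Capsule(joints[na], joints[nb], r))
    return CapsuleBody(capsules=capsules, skeleton=Skeleton(joints=joints, bones=bones))


def _humanoid(r_arm_pose: str) -> CapsuleBody:
    """15-joint humanoid; arms in t-pose or with the right arm lowered
    alongside the torso ('armpit'), leaving a narrow occluded wedge."""
    J = {
        "pelvis": (0.0, 0.0, 1.60),
        "neck": (0.0, 0.0, 2.10),
        "head": (0.0, 0.0, 2.38),
        "l_shoulder": (-0.22, 0.0, 2.05),
        "l_elbow": (-0.52, 0.0, 2.05),
        "l_wrist": (-0.80, 0.0, 2.05),
        "r_shoulder": (0.22, 0.0, 2.05),
        "r_elbow": (0.52, 0.0, 2.05),
        "r_wrist": (0.80, 0.0, 2.05),
        "l_hip": (-0.11, 0.0, 1.52),
        "l_knee": (-0.14, 0.0, 1.12),
        "l_ankle": (-0.16, 0.0, 0.72),
        "r_hip": (0.11, 0.0, 1.52),
        "r_knee": (0.14, 0.0, 1.12),
        "r_ankle": (0.16, 0.0, 0.72),
    }
    if r_arm_pose == "lowered":
        # right arm close to the torso: deep wedge at the armpit
        J["r_elbow"] = (0.30, 0.0, 1.70)
        J["r_wrist"] = (0.33, 0.0, 1.36)
    pairs = [
        ("head", J["head"], "neck", J["neck"]),
        ("neck", J["neck"], "l_shoulder", J["l_shoulder"]),
        ("l_shoulder", J["l_shoulder"], "l_elbow", J["l_elbow"]),
        ("l_elbow", J["l_elbow"], "l_wrist", J["l_wrist"]),
        ("neck", J["neck"], "r_shoulder", J["r_shoulder"]),
        ("r_shoulder", J["r_shoulder"], "r_elbow", J["r_elbow"]),
        ("r_elbow", J["r_elbow"], "r_wrist", J["r_wrist"]),
        ("pelvis", J["pelvis"], "neck", J["neck"]),
        ("pelvis", J["pelvis"], "l_hip", J["l_hip"]),
        ("l_hip", J["l_hip"], "l_knee", J["l_knee"]),
        ("l_knee", J["l_knee"], "l_ankle", J["l_ankle"]),
        ("pelvis", J["pelvis"], "r_hip", J["r_hip"]),
        ("r_hip", J["r_hip"], "r_knee", J["r_knee"]),
        ("r_knee", J["r_knee"], "r_ankle", J["r_ankle"]),
    ]
    radii = [0.10, 0.06, 0.05, 0.045, 0.06, 0.05, 0.045, 0.14, 0.08, 0.07, 0.055, 0.08,
             0.07, 0.055]
    return _skeleton_from_pairs(pairs, radii)


def _sphere_body() -> CapsuleBody:
    c = np.array([0.0, 0.0, 1.6])
    joints = {"center_a": c, "center_b": c.copy()}
    sk = Skeleton(joints=joints, bones=[("center_a", "center_b")])
    return CapsuleBody(capsules=[Capsule(c, c, 0.3)], skeleton=sk)


def _one_bone_body() -> CapsuleBody:
    a = np.array([0.0, 0.0, 1.1])
    b = np.array([0.0, 0.0, 2.1])
    sk = Skeleton(joints={"bottom": a, "top": b}, bones=[("bottom", "top")])
    return CapsuleBody(capsules=[Capsule(a, b, 0.22)], skeleton=sk)


def _l_pose_body() -> CapsuleBody:
    a = np.array([0.0, 0.0, 1.0])
    b = np.array([0.0, 0.0, 2.0])
    c = np.array([0.75, 0.0, 2.0])
    sk = Skeleton(joints={"base": a, "corner": b, "tip": c},
                  bones=[("base", "corner"), ("corner", "tip")])
    return CapsuleBody(capsules=[Capsule(a, b, 0.16), Capsule(b, c, 0.12)], skeleton=sk)


POSES = {
    "sphere": _sphere_body,
    "t-pose": lambda: _humanoid("t"),
    "armpit": lambda: _humanoid("lowered"),
    "one-bone": _one_bone_body,
    "l-pose": _l_pose_body,
}


def make_body(pose: str) -> CapsuleBody:
    """Deterministic capsule body + skeleton for a named pose."""
    try:
        factory = POSES[pose]
    except KeyError:
        raise ValueError(f"unknown pose {pose!r}; available: {sorted(POSES)}") from None
    return factory()


# ---------------------------------------------------------------------------
# analytic capsule geometry

def _capsule_signed_distance(points: np.ndarray, cap: Capsule) -> np.ndarray:
    u = cap.b - cap.a
    uu = float(u @ u)
    w = points - cap.a
    if uu > 0:
        t = np.clip((w @ u) / uu, 0.0, 1.0)
    else:
        t = np.zeros(points.shape[0])
    closest = cap.a + t[:, None] * u
    return np.linalg.norm(points - closest, axis=1) - cap.radius


def _ray_segment_distance(origin: np.ndarray, dirs: np.ndarray,
                          p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    """Min distance from rays (origin, unit dirs (n,3), s >= 0) to segment p0->p1."""
    u = p1 - p0
    c = float(u @ u)
    w0 = origin - p0
    dd = dirs @ w0          # d . w0
    e_ = np.full(dirs.shape[0], float(u @ w0))
    if c > 0:
        b = dirs @ u
        denom = c - b * b
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.where(denom > 1e-12, (b * e_ - c * dd) / np.where(denom > 1e-12, denom, 1.0), 0.0)
        s = np.maximum(s, 0.0)
        t = np.clip((e_ + s * b) / c, 0.0, 1.0)
        s = np.maximum(t * b - dd, 0.0)
    else:
        t = np.zeros(dirs.shape[0])
        s = np.maximum(-dd, 0.0)
    diff = (origin + s[:, None] * dirs) - (p0 + t[:, None] * u)
    return np.linalg.norm(diff, axis=1)


def _pixel_rays(camera: CameraModel):
    """World-space unit directions of all pixel-center rays, shape (h*w, 3)."""
    us = (np.arange(camera.width) + 0.5 - camera.cx) / camera.fx
    vs = (np.arange(camera.height) + 0.5 - camera.cy) / camera.fy
    uu, vv = np.meshgrid(us, vs)
    d_cam = np.column_stack([uu.ravel(), vv.ravel(), np.ones(uu.size)])
    d_world = d_cam @ camera.rotation
    d_world /= np.linalg.norm(d_world, axis=1, keepdims=True)
    return d_world


def render_silhouette(
    body: CapsuleBody,
    camera: CameraModel,
    noise: Optional[SilhouetteNoiseModel] = None,
    conservative: bool = False,
) -> ProbabilitySilhouette:
    """Ray-trace the exact binary silhouette, then apply optional noise.

    A pixel is 255 iff its center ray intersects any capsule (no
    antialiasing), so the clean image has an exact per-pixel oracle.  The
    soft edge band and blob noise are explicit seeded post-processes.

    With ``conservative=True`` the binary mask is dilated by one pixel
    (8-connected) before noise, approximating conservative rasterization
    (pixel marked iff its square touches the projected region).  Only a
    conservative silhouette makes the visual hull a guaranteed superset of
    the body at threshold 1: with pixel-center sampling a voxel center just
    inside the surface may fall into an unmarked rim pixel of a grazing
    view.
    """
    origin = camera.center
    dirs = _pixel_rays(camera)
    hit = np.zeros(dirs.shape[0], dtype=bool)
    for cap in body.capsules:
        todo = ~hit
        if not todo.any():
            break
        d = _ray_segment_distance(origin, dirs[todo], cap.a, cap.b)
        sub = hit[todo]
        sub |= d <= cap.radius
        hit[todo] = sub
    hit2d = hit.reshape(camera.height, camera.width)
    if conservative:
        hit2d = ndimage.binary_dilation(hit2d, structure=np.ones((3, 3), dtype=bool))
    img = np.where(hit2d, np.uint8(255), np.uint8(0))
    if noise is not None:
        img = _apply_noise(img, noise)
    return ProbabilitySilhouette(img, camera_id=camera.camera_id)


def _apply_noise(img: np.ndarray, noise: SilhouetteNoiseModel) -> np.ndarray:
    rng = np.random.default_rng(noise.seed)
    out = img.copy()
    lo, hi = noise.value_range
    if noise.edge_band > 0 and img.any() and not img.all():
        inside = img == 255
        d_in = ndimage.distance_transform_edt(inside)
        d_out = ndimage.distance_transform_edt(~inside)
        signed = np.where(inside, d_in, -d_out)
        band = np.abs(signed) <= noise.edge_band
        frac = 0.5 * (1.0 + signed[band] / noise.edge_band)
        frac = frac + rng.normal(0.0, noise.edge_roughness, size=frac.shape)
        vals = np.clip(np.rint(lo + frac * (hi - lo)), lo, hi).astype(np.uint8)
        out[band] = vals
    if noise.blob_rate > 0:
        h, w = img.shape
        n_blobs = rng.poisson(noise.blob_rate)
        boundary = None
        if noise.blob_placement == "boundary" and img.any() and not img.all():
            inside = img == 255
            edge = inside & ~ndimage.binary_erosion(inside)
            boundary = np.argwhere(edge)
        yy, xx = np.mgrid[0:h, 0:w]
        for _ in range(n_blobs):
            if boundary is not None and boundary.shape[0]:
                cy, cx = boundary[rng.integers(boundary.shape[0])]
            else:
                cy = rng.uniform(0, h)
                cx = rng.uniform(0, w)
            r = max(1.0, rng.normal(noise.blob_size, noise.blob_size / 3.0))
            val = np.uint8(rng.integers(lo, hi + 1))
            blob = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
            out[blob] = val
    return out


def project_joints(
    skeleton: Skeleton,
    cameras: Sequence[CameraModel],
    sigma: float = 0.0,
    seed: int = 0,
) -> Dict[str, Dict[str, Tuple[float, float]]]:
    """Noiseless joint projections plus seeded Gaussian pixel noise.

    Joints behind a camera or outside its frame are omitted (missing).
    Returns ``{camera_id: {joint_name: (u, v)}}``.
    """
    if sigma < 0:
        raise ValueError("noise sigma must be non-negative")
    rng = np.random.default_rng(seed)
    names = list(skeleton.joints)
    pts = np.array([skeleton.joints[n] for n in names])
    detections: Dict[str, Dict[str, Tuple[float, float]]] = {}
    for cam in cameras:
        uv, in_front = project_points(cam, pts)
        per_cam: Dict[str, Tuple[float, float]] = {}
        noise = rng.normal(0.0, sigma, size=uv.shape) if sigma > 0 else np.zeros_like(uv)
        for i, name in enumerate(names):
            if not in_front[i]:
                continue
            u, v = uv[i]
            if not (0 <= u < cam.width and 0 <= v < cam.height):
                continue
            u = float(np.clip(u + noise[i, 0], 0.0, cam.width - 1e-6))
            v = float(np.clip(v + noise[i, 1], 0.0, cam.height - 1e-6))
            per_cam[name] = (u, v)
        detections[cam.camera_id] = per_cam
    return detections


def sample_reference(body: CapsuleBody, n: int, seed: int = 0):
    """Uniform-area samples on the capsule-union boundary with exact normals.

    Points falling strictly inside another capsule are rejected, so every
    returned point lies on the boundary of the union.  Returns a
    :class:`~voxelhull.evaluation.ReferenceSurface`.
    """
    from .evaluation import ReferenceSurface

    if n < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    areas = []
    for cap in body.capsules:
        length = float(np.linalg.norm(cap.b - cap.a))
        areas.append(2.0 * math.pi * cap.radius * length + 4.0 * math.pi * cap.radius ** 2)
    areas = np.array(areas)
    probs = areas / areas.sum()
    pts_out: List[np.ndarray] = []
    nrm_out: List[np.ndarray] = []
    got = 0
    for _ in range(1000):  # rejection rounds
        batch = max(n - got, 256)
        which = rng.choice(len(body.capsules), size=batch, p=probs)
        pts = np.empty((batch, 3))
        nrm = np.empty((batch, 3))
        for ci in np.unique(which):
            sel = np.where(which == ci)[0]
            p, m = _sample_capsule_surface(body.capsules[ci], sel.size, rng)
            pts[sel] = p
            nrm[sel] = m
        # reject points strictly inside any *other* capsule
        keep = np.ones(batch, dtype=bool)
        for cj, cap in enumerate(body.capsules):
            inside = _capsule_signed_distance(pts, cap) < -1e-9
            own = which == cj
            keep &= ~(inside & ~own)
        pts_out.append(pts[keep])
        nrm_out.append(nrm[keep])
        got += int(keep.sum())
        if got >= n:
            break
    points = np.concatenate(pts_out)[:n]
    normals = np.concatenate(nrm_out)[:n]
    if points.shape[0] < n:
        raise RuntimeError("surface sampling failed to converge")
    return ReferenceSurface(points=points, normals=normals)


def _sample_capsule_surface(cap: Capsule, count: int, rng) -> Tuple[np.ndarray, np.ndarray]:
    u = cap.b - cap.a
    length = float(np.linalg.norm(u))
    r = cap.radius
    lateral_area = 2.0 * math.pi * r * length
    cap_area = 4.0 * math.pi * r * r
    p_lat = lateral_area / (lateral_area + cap_area)
    on_lat = rng.random(count) < p_lat
    pts = np.empty((count, 3))
    nrm = np.empty((count, 3))
    if length > 0:
        axis = u / length
    else:
        axis = np.array([0.0, 0.0, 1.0])
    # orthonormal frame around the axis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    n_lat = int(on_lat.sum())
    if n_lat:
        t = rng.random(n_lat) * length
        phi = rng.random(n_lat) * 2.0 * math.pi
        radial = np.outer(np.cos(phi), e1) + np.outer(np.sin(phi), e2)
        pts[on_lat] = cap.a + np.outer(t, axis) + r * radial
        nrm[on_lat] = radial
    n_cap = count - n_lat
    if n_cap:
        # uniform on the full sphere, attached to the far/near endpoint by hemisphere
        v = rng.normal(size=(n_cap, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        ends = np.where((v @ axis)[:, None] >= 0, cap.b, cap.a)
        pts[~on_lat] = ends + r * v
        nrm[~on_lat] = v
    return pts, nrm
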