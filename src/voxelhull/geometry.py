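"""Calibrated pinhole camera geometry.

Conventions
-----------
* World-to-camera pose is stored as ``(R, t)`` with ``x_cam = R @ x_world + t``.
* The camera looks along +z of its own frame; a point is "in front" iff
  ``z_cam > 0``.
* Continuous pixel coordinates have their origin at the top-left image
  corner, ``u`` growing rightward and ``v`` downward.  Pixel ``(i, j)``
  covers the half-open square ``[i, i+1) x [j, j+1)``, so an integer pixel
  is obtained from continuous coordinates by ``floor``.
* No lens distortion model: images are assumed pre-undistorted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DegenerateGeometryError

__all__ = [
    "CameraModel",
    "Ray",
    "Aabb",
    "project",
    "project_points",
    "pixel_ray",
    "triangulate_rays",
    "rig_bounding_box",
]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class CameraModel:
    """A calibrated pinhole view.

    Parameters
    ----------
    fx, fy : float
        Focal lengths in pixels; must be positive.
    cx, cy : float
        Principal point in pixels.
    rotation : (3, 3) array
        World-to-camera rotation; must be orthonormal with determinant +1.
    translation : (3,) array
        World-to-camera translation in meters.
    width, height : int
        Image dimensions in pixels.
    camera_id : str
        Free-form identifier used to pair cameras with image files.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    rotation: np.ndarray
    translation: np.ndarray
    width: int
    height: int
    camera_id: str = ""

    def __post_init__(self) -> None:
        R = np.array(self.rotation, dtype=float).reshape(3, 3)
        t = np.array(self.translation, dtype=float).reshape(3)
        R.setflags(write=False)
        t.setflags(write=False)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not (self.fx > 0 and self.fy > 0):
            raise ValueError("focal lengths must be positive")
        if self.width < 1 or self.height < 1:
            raise ValueError("image dimensions must be at least 1x1")
        if np.abs(R @ R.T - np.eye(3)).max() > _ORTHO_TOL:
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > _ORTHO_TOL:
            raise ValueError("rotation determinant must be +1")

    @property
    def center(self) -> np.ndarray:
        """Camera center in world coordinates, ``-R.T @ t``."""
        return -self.rotation.T @ self.translation

    def world_to_camera(self, points: np.ndarray) -> np.ndarray:
        """Map (..., 3) world points into the camera frame."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation


@dataclass(frozen=True)
class Ray:
    """A half-line with unit direction."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        o = np.array(self.origin, dtype=float).reshape(3)
        d = np.array(self.direction, dtype=float).reshape(3)
        if abs(np.linalg.norm(d) - 1.0) > 1e-12:
            raise ValueError("ray direction must be a unit vector")
        o.setflags(write=False)
        d.setflags(write=False)
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d)


@dataclass(frozen=True)
class Aabb:
    """Axis-aligned bounding box; ``min_corner <= max_corner`` componentwise."""

    min_corner: np.ndarray
    max_corner: np.ndarray

    def __post_init__(self) -> None:
        lo = np.array(self.min_corner, dtype=float).reshape(3)
        hi = np.array(self.max_corner, dtype=float).reshape(3)
        if np.any(lo > hi):
            raise ValueError("Aabb min corner exceeds max corner")
        lo.setflags(write=False)
        hi.setflags(write=False)
        object.__setattr__(self, "min_corner", lo)
        object.__setattr__(self, "max_corner", hi)

    @property
    def extent(self) -> np.ndarray:
        return self.max_corner - self.min_corner

    def expanded(self, margin: float) -> "Aabb":
        return Aabb(self.min_corner - margin, self.max_corner + margin)

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return np.all((pts >= self.min_corner) & (pts <= self.max_corner), axis=-1)


def project_points(camera: CameraModel, points: np.ndarray):
    """Project (n, 3) world points; returns ``(uv, in_front)``.

    ``uv`` holds continuous pixel coordinates (n, 2).  Points behind the
    camera (``z_cam <= 0``) get non-finite or meaningless coordinates and
    ``in_front`` False; callers must gate on the flag.
    """
    pc = camera.world_to_camera(np.atleast_2d(points))
    z = pc[:, 2]
    in_front = z > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        u = camera.fx * pc[:, 0] / z + camera.cx
        v = camera.fy * pc[:, 1] / z + camera.cy
    return np.column_stack([u, v]), in_front


def project(camera: CameraModel, point: np.ndarray):
    """Scalar convenience wrapper around :func:`project_points`."""
    uv, in_front = project_points(camera, np.asarray(point, dtype=float).reshape(1, 3))
    return uv[0], bool(in_front[0])


def pixel_ray(camera: CameraModel, pixel: np.ndarray) -> Ray:
    """Back-project a continuous pixel coordinate into a world-space ray.

    The ray starts at the camera center; for any point ``p`` in front of the
    camera, ``pixel_ray(camera, project(camera, p)[0])`` passes through ``p``.
    """
    u, v = float(pixel[0]), float(pixel[1])
    d_cam = np.array([(u - camera.cx) / camera.fx, (v - camera.cy) / camera.fy, 1.0])
    d_world = camera.rotation.T @ d_cam
    d_world /= np.linalg.norm(d_world)
    return Ray(camera.center, d_world)


def triangulate_rays(rays: Sequence[Ray]) -> np.ndarray:
    """Least-squares intersection of ray *lines*.

    Returns the 3D point minimizing the sum of squared perpendicular
    distances to all ray lines, via the 3x3 normal equations
    ``sum_i (I - d_i d_i^T) x = sum_i (I - d_i d_i^T) o_i``.

    Raises
    ------
    DegenerateGeometryError
        If fewer than two rays are given or all directions are parallel
        (rank-deficient system).
    """
    if len(rays) < 2:
        raise DegenerateGeometryError("triangulation requires at least 2 rays")
    A = np.zeros((3, 3))
    b = np.zeros(3)
    for ray in rays:
        d = ray.direction
        M = np.eye(3) - np.outer(d, d)
        A += M
        b += M @ ray.origin
    w = np.linalg.eigvalsh(A)
    if w[0] < 1e-9 * max(w[-1], 1.0):
        raise DegenerateGeometryError("rays are (nearly) all parallel")
    return np.linalg.solve(A, b)


def rig_bounding_box(cameras: Sequence[CameraModel]) -> Aabb:
    """Axis-aligned bounding box of the camera centers.

    Raises
    ------
    DegenerateGeometryError
        If fewer than two cameras are given or all centers coincide.
    """
    if len(cameras) < 2:
        raise DegenerateGeometryError("rig bounding box requires at least 2 cameras")
    centers = np.array([c.center for c in cameras])
    lo = centers.min(axis=0)
    hi = centers.max(axis=0)
    if np.all(hi - lo <= 0):
        raise DegenerateGeometryError("all camera centers coincide")
    return Aabb(lo, hi)
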