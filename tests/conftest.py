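"""Shared fixtures: cameras, small rigs, and reusable rendered scenes."""

from __future__ import annotations

import numpy as np
import pytest

import voxelhull as vh
from voxelhull.synthetic import _look_at_rotation


def look_at_camera(position, target=(0.0, 0.0, 0.0), f=200.0, width=200, height=200,
                   camera_id="cam"):
    """Camera at ``position`` aimed at ``target`` (test helper)."""
    position = np.asarray(position, dtype=float)
    R = _look_at_rotation(position, np.asarray(target, dtype=float))
    return vh.CameraModel(
        fx=f, fy=f, cx=width / 2.0, cy=height / 2.0,
        rotation=R, translation=-R @ position,
        width=width, height=height, camera_id=camera_id,
    )


def random_camera(rng, target=(0.0, 0.0, 0.0), radius=3.0, f=200.0, size=200,
                  camera_id="cam"):
    """Random camera on a sphere around ``target``, aimed at it."""
    d = rng.normal(size=3)
    d /= np.linalg.norm(d)
    pos = np.asarray(target, dtype=float) + radius * d
    return look_at_camera(pos, target, f=f, width=size, height=size, camera_id=camera_id)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def simple_camera():
    """Identity pose, fx=fy=100, cx=cy=50, 100x100 image."""
    return vh.CameraModel(
        fx=100.0, fy=100.0, cx=50.0, cy=50.0,
        rotation=np.eye(3), translation=np.zeros(3),
        width=100, height=100, camera_id="simple",
    )


@pytest.fixture(scope="session")
def default_rig():
    """The standard 34-camera rig at 512x512."""
    return vh.make_rig(vh.RigSpec(image_size=(512, 512)))


@pytest.fixture(scope="session")
def sphere_body():
    return vh.make_body("sphere")


@pytest.fixture(scope="session")
def sphere_silhouettes_conservative(default_rig, sphere_body):
    """Exact binary silhouettes of the sphere with conservative rasterization."""
    return [vh.render_silhouette(sphere_body, c, conservative=True) for c in default_rig]


@pytest.fixture(scope="session")
def small_rig():
    """Cheap 12-camera rig with 128x128 images for fast end-to-end tests."""
    spec = vh.RigSpec(n_columns=5, cameras_per_column=2, n_ceiling=2,
                      image_size=(128, 128))
    return vh.make_rig(spec)
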