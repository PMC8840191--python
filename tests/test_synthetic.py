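import numpy as np
import pytest

import voxelhull as vh
from voxelhull.synthetic import POSES, _capsule_signed_distance

from conftest import look_at_camera


class TestMakeRig:
    def test_default_has_34_cameras(self, default_rig):
        assert len(default_rig) == 34

    def test_heights_within_bounds(self, default_rig):
        z = np.array([c.center[2] for c in default_rig])
        assert z.min() >= 0.5 - 1e-9
        assert z.max() <= 3.5 + 1e-9

    def test_single_camera_rig(self):
        spec = vh.RigSpec(n_columns=1, cameras_per_column=1, n_ceiling=0)
        assert len(vh.make_rig(spec)) == 1

    def test_zero_cameras_rejected(self):
        with pytest.raises(ValueError):
            vh.RigSpec(n_columns=0, cameras_per_column=0, n_ceiling=0)

    def test_cameras_aim_at_target(self, default_rig):
        target = np.array([0.0, 0.0, 1.6])
        for cam in default_rig[::7]:
            uv, in_front = vh.project(cam, target)
            assert in_front
            assert np.allclose(uv, [cam.cx, cam.cy], atol=1e-9)

    def test_unique_ids(self, default_rig):
        ids = [c.camera_id for c in default_rig]
        assert len(set(ids)) == len(ids)


class TestMakeBody:
    def test_sphere_is_single_zero_length_capsule(self):
        body = vh.make_body("sphere")
        assert len(body.capsules) == 1
        cap = body.capsules[0]
        assert np.allclose(cap.a, cap.b)

    def test_tpose_has_14_capsules_and_symmetry(self):
        body = vh.make_body("t-pose")
        assert len(body.capsules) == 14
        J = body.skeleton.joints
        for left in [n for n in J if n.startswith("l_")]:
            right = "r_" + left[2:]
            mirrored = J[left] * np.array([-1.0, 1.0, 1.0])
            assert np.allclose(mirrored, J[right])

    @pytest.mark.parametrize("pose", sorted(POSES))
    def test_capsule_endpoints_equal_bone_joints(self, pose):
        body = vh.make_body(pose)
        a, b = body.skeleton.bone_endpoints()
        for i, cap in enumerate(body.capsules):
            assert np.allclose(cap.a, a[i])
            assert np.allclose(cap.b, b[i])

    def test_unknown_pose(self):
        with pytest.raises(ValueError):
            vh.make_body("handstand")


class TestRenderSilhouette:
    def test_camera_looking_away_gives_empty_image(self):
        body = vh.make_body("sphere")
        cam = look_at_camera([0, 0, 5.0], target=[0, 0, 20.0], f=100.0,
                             width=64, height=64)
        sil = vh.render_silhouette(body, cam)
        assert not sil.values.any()

    def test_noise_free_image_is_binary(self, default_rig, sphere_body):
        sil = vh.render_silhouette(sphere_body, default_rig[0])
        assert set(np.unique(sil.values)) <= {0, 255}
        assert (sil.values == 255).any()

    def test_matches_scalar_ray_oracle(self):
        """Per-pixel scalar ray-capsule test reproduces the rendered image."""
        body = vh.make_body("l-pose")
        cam = look_at_camera([2.5, 0.6, 1.5], target=[0.2, 0, 1.5], f=40.0,
                             width=48, height=48)
        sil = vh.render_silhouette(body, cam)
        from scipy.optimize import minimize_scalar

        o = cam.center
        for v in range(48):
            for u in range(48):
                ray = vh.pixel_ray(cam, [u + 0.5, v + 0.5])
                # oracle: 1D convex minimization of distance along the ray
                dmin = np.inf
                for cap in body.capsules:
                    res = minimize_scalar(
                        lambda t, c=cap: float(
                            _capsule_signed_distance(
                                (o + t * ray.direction)[None, :], c
                            )[0]
                        ),
                        bounds=(0.0, 10.0),
                        method="bounded",
                        options={"xatol": 1e-10},
                    )
                    dmin = min(dmin, res.fun)
                if abs(dmin) < 1e-6:
                    continue  # grazing pixel: both answers acceptable
                assert (sil.values[v, u] == 255) == (dmin < 0), (u, v)

    def test_sphere_disk_boundary_within_one_pixel(self, sphere_body):
        cam = look_at_camera([3.0, 0.0, 1.6], target=[0, 0, 1.6], f=120.0,
                             width=128, height=128)
        sil = vh.render_silhouette(sphere_body, cam)
        center = sphere_body.capsules[0].a
        r = sphere_body.capsules[0].radius
        # analytic outline: pixel is foreground iff its center ray passes
        # within r of the sphere center
        for v in range(0, 128, 3):
            for u in range(0, 128, 3):
                ray = vh.pixel_ray(cam, [u + 0.5, v + 0.5])
                d = np.linalg.norm(np.cross(center - ray.origin, ray.direction))
                if d < r - 0.01:
                    assert sil.values[v, u] == 255
                elif d > r + 0.01:
                    assert sil.values[v, u] == 0

    def test_noise_values_stay_in_range(self, sphere_body):
        cam = look_at_camera([3.0, 0.0, 1.6], target=[0, 0, 1.6], f=100.0,
                             width=96, height=96)
        noise = vh.SilhouetteNoiseModel(edge_band=2.0, blob_rate=3.0, seed=5)
        sil = vh.render_silhouette(sphere_body, cam, noise)
        band = (sil.values > 0) & (sil.values < 255)
        assert band.any()

    def test_noise_is_seed_deterministic(self, sphere_body):
        cam = look_at_camera([3.0, 0.0, 1.6], target=[0, 0, 1.6], f=100.0,
                             width=96, height=96)
        noise = vh.SilhouetteNoiseModel(edge_band=2.0, blob_rate=2.0, seed=9)
        a = vh.render_silhouette(sphere_body, cam, noise)
        b = vh.render_silhouette(sphere_body, cam, noise)
        assert np.array_equal(a.values, b.values)

    def test_conservative_is_superset(self, sphere_body, default_rig):
        cam = default_rig[0]
        plain = vh.render_silhouette(sphere_body, cam)
        cons = vh.render_silhouette(sphere_body, cam, conservative=True)
        assert np.all(cons.values >= plain.values)


class TestProjectJoints:
    def test_round_trip_noiseless(self, default_rig):
        body = vh.make_body("armpit")
        det = vh.project_joints(body.skeleton, default_rig, sigma=0.0)
        sk = vh.triangulate_skeleton(det, default_rig)
        for name, truth in body.skeleton.joints.items():
            assert np.linalg.norm(sk.joints[name] - truth) < 1e-6

    def test_seed_determinism(self, default_rig):
        body = vh.make_body("t-pose")
        a = vh.project_joints(body.skeleton, default_rig, sigma=2.0, seed=3)
        b = vh.project_joints(body.skeleton, default_rig, sigma=2.0, seed=3)
        assert a == b

    def test_joint_behind_camera_missing(self):
        sk = vh.Skeleton(joints={"a": [0, 0, 5.0], "b": [0, 0, -5.0]},
                         bones=[("a", "b")])
        cam = look_at_camera([0, 0, 0.0], target=[0, 0, 10.0], f=100.0)
        det = vh.project_joints(sk, [cam])
        assert "a" in det[cam.camera_id]
        assert "b" not in det[cam.camera_id]


class TestSampleReference:
    def test_sphere_points_radial(self):
        body = vh.make_body("sphere")
        ref = vh.sample_reference(body, 500, seed=4)
        center = body.capsules[0].a
        radii = np.linalg.norm(ref.points - center, axis=1)
        assert np.allclose(radii, 0.3, atol=1e-9)
        radial = (ref.points - center) / radii[:, None]
        assert np.allclose(ref.normals, radial, atol=1e-9)

    @pytest.mark.parametrize("pose", ["armpit", "l-pose", "one-bone"])
    def test_points_on_union_boundary(self, pose):
        body = vh.make_body(pose)
        ref = vh.sample_reference(body, 800, seed=2)
        sd = body.signed_distance(ref.points)
        assert np.max(np.abs(sd)) < 1e-9

    def test_seed_reproducible(self):
        body = vh.make_body("t-pose")
        a = vh.sample_reference(body, 300, seed=8)
        b = vh.sample_reference(body, 300, seed=8)
        assert np.array_equal(a.points, b.points)
        assert np.array_equal(a.normals, b.normals)

    def test_normals_match_numeric_gradient(self):
        """Away from seams, normals agree with the signed-distance gradient."""
        body = vh.make_body("one-bone")
        ref = vh.sample_reference(body, 300, seed=6)
        eps = 1e-6
        grads = np.zeros_like(ref.points)
        for ax in range(3):
            step = np.zeros(3)
            step[ax] = eps
            grads[:, ax] = (
                body.signed_distance(ref.points + step)
                - body.signed_distance(ref.points - step)
            ) / (2 * eps)
        grads /= np.linalg.norm(grads, axis=1, keepdims=True)
        ang = np.arccos(np.clip(np.einsum("ij,ij->i", grads, ref.normals), -1, 1))
        assert np.max(ang) < 1e-4

    def test_needs_positive_count(self):
        with pytest.raises(ValueError):
            vh.sample_reference(vh.make_body("sphere"), 0)


class TestCapsuleBody:
    def test_contains_center(self):
        body = vh.make_body("one-bone")
        assert body.contains([[0.0, 0.0, 1.5]])[0]
        assert not body.contains([[1.0, 1.0, 1.5]])[0]

    def test_mismatched_capsule_endpoints_rejected(self):
        sk = vh.Skeleton(joints={"a": [0, 0, 0], "b": [0, 0, 1.0]}, bones=[("a", "b")])
        from voxelhull.synthetic import Capsule

        with pytest.raises(ValueError):
            vh.CapsuleBody(capsules=[Capsule([0, 0, 0], [0, 0, 2.0], 0.1)], skeleton=sk)
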