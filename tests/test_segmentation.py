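import numpy as np
import pytest

import voxelhull as vh
from voxelhull.errors import (
    EmptyProjectionError,
    IncompleteSkeletonError,
    InputMismatchError,
)
from voxelhull.segmentation import point_segment_distances

from conftest import look_at_camera


def _sil(arr):
    return vh.ProbabilitySilhouette(np.asarray(arr, dtype=np.uint8))


class TestSkeleton:
    def test_requires_known_joints(self):
        with pytest.raises(ValueError):
            vh.Skeleton(joints={"a": [0, 0, 0]}, bones=[("a", "b")])

    def test_requires_distinct_endpoints(self):
        with pytest.raises(ValueError):
            vh.Skeleton(joints={"a": [0, 0, 0]}, bones=[("a", "a")])

    def test_requires_bones(self):
        with pytest.raises(ValueError):
            vh.Skeleton(joints={"a": [0, 0, 0], "b": [1, 0, 0]}, bones=[])


class TestTriangulateSkeleton:
    def test_noiseless_recovery(self, default_rig):
        body = vh.make_body("t-pose")
        det = vh.project_joints(body.skeleton, default_rig, sigma=0.0)
        sk = vh.triangulate_skeleton(det, default_rig)
        for name, truth in body.skeleton.joints.items():
            assert np.linalg.norm(sk.joints[name] - truth) < 1e-6

    def test_joint_seen_once_is_absent(self, default_rig):
        body = vh.make_body("t-pose")
        det = vh.project_joints(body.skeleton, default_rig, sigma=0.0)
        # keep 'head' in a single view only
        first = True
        for cam_id in list(det):
            if "head" in det[cam_id]:
                if first:
                    first = False
                else:
                    del det[cam_id]["head"]
        with pytest.raises(IncompleteSkeletonError) as exc:
            vh.triangulate_skeleton(det, default_rig)
        assert "head" in exc.value.missing

    def test_noise_error_decreases_with_sigma(self, default_rig):
        """Seeded decreasing-noise sweep is monotone within sampling error."""
        body = vh.make_body("t-pose")
        errs = []
        for sigma in (4.0, 1.0, 0.25):
            det = vh.project_joints(body.skeleton, default_rig, sigma=sigma, seed=11)
            sk = vh.triangulate_skeleton(det, default_rig)
            errs.append(
                max(
                    np.linalg.norm(sk.joints[n] - body.skeleton.joints[n])
                    for n in body.skeleton.joints
                )
            )
        assert errs[0] > errs[1] > errs[2]


class TestAssignToBones:
    def _skeleton(self):
        return vh.Skeleton(
            joints={"a0": [0, 0, 0], "a1": [1, 0, 0], "b0": [0, 1, 0], "b1": [1, 1, 0]},
            bones=[("a0", "a1"), ("b0", "b1")],
        )

    def test_nearest_bone(self):
        labels = vh.assign_to_bones([[0.5, 0.2, 0.0]], self._skeleton())
        assert labels.tolist() == [0]

    def test_tie_breaks_to_lowest_index(self):
        labels = vh.assign_to_bones([[0.5, 0.5, 0.0]], self._skeleton())
        assert labels.tolist() == [0]

    def test_matches_bruteforce_table(self, rng):
        body = vh.make_body("t-pose")
        sk = body.skeleton
        pts = rng.uniform([-1, -1, 0.5], [1, 1, 2.5], size=(1000, 3))
        labels = vh.assign_to_bones(pts, sk)
        a, b = sk.bone_endpoints()

        def seg_dist(p, s, e):
            u = e - s
            uu = u @ u
            t = float(np.clip((p - s) @ u / uu, 0, 1)) if uu > 0 else 0.0
            return np.linalg.norm(p - (s + t * u))

        for p, lab in zip(pts, labels):
            d = [seg_dist(p, a[i], b[i]) for i in range(len(sk.bones))]
            assert lab == int(np.argmin(d))

    def test_partition_property(self, rng):
        body = vh.make_body("armpit")
        pts = rng.uniform([-1, -1, 0.5], [1, 1, 2.5], size=(500, 3))
        labels = vh.assign_to_bones(pts, body.skeleton)
        assert labels.shape == (500,)
        assert np.all((labels >= 0) & (labels < len(body.skeleton.bones)))

    def test_zero_length_bone(self):
        sk = vh.Skeleton(joints={"a": [0, 0, 0], "b": [0, 0, 0]}, bones=[("a", "b")])
        assert vh.assign_to_bones([[1, 2, 3]], sk).tolist() == [0]


class TestPointSegmentDistances:
    def test_closed_forms(self):
        d = point_segment_distances(
            np.array([[0.5, 1.0, 0.0], [2.0, 0.0, 0.0], [-3.0, 4.0, 0.0]]),
            np.array([[0.0, 0.0, 0.0]]),
            np.array([[1.0, 0.0, 0.0]]),
        )
        assert np.allclose(d[:, 0], [1.0, 1.0, 5.0])


class TestRenderSegmentMask:
    def test_empty_segment_all_zero(self, simple_camera):
        mask = vh.render_segment_mask(np.zeros((0, 3)), 0.1, simple_camera)
        assert mask.shape == (100, 100)
        assert not mask.any()

    def test_behind_camera_all_zero(self, simple_camera):
        mask = vh.render_segment_mask([[0.0, 0.0, -2.0]], 0.1, simple_camera)
        assert not mask.any()

    def test_disk_covers_corner_projections(self, rng):
        """Oracle: the pixel hull of the voxel cube's 8 corners is covered."""
        cam = look_at_camera([0, 0, 2.0], target=[0, 0, 0], f=150.0)
        for _ in range(25):
            c = rng.uniform(-0.3, 0.3, size=3)
            d = rng.uniform(0.02, 0.15)
            mask = vh.render_segment_mask([c], d, cam)
            half = d / 2.0
            for sx in (-half, half):
                for sy in (-half, half):
                    for sz in (-half, half):
                        uv, in_front = vh.project(cam, c + np.array([sx, sy, sz]))
                        assert in_front
                        iu, iv = int(np.floor(uv[0])), int(np.floor(uv[1]))
                        if 0 <= iu < cam.width and 0 <= iv < cam.height:
                            assert mask[iv, iu] == 255

    def test_zero_radius_reproduces_dots(self, simple_camera):
        mask = vh.render_segment_mask([[0.0, 0.0, 1.0]], 0.01, simple_camera,
                                      dilation_radius=0)
        assert mask.sum() == 255
        assert mask[50, 50] == 255

    def test_union_over_segments_equals_whole_set(self, rng):
        cam = look_at_camera([0, 0, 3.0], target=[0, 0, 0], f=120.0)
        pts = rng.uniform(-0.4, 0.4, size=(60, 3))
        labels = rng.integers(0, 3, size=60)
        whole = vh.render_segment_mask(pts, 0.05, cam)
        union = np.zeros_like(whole)
        for s in range(3):
            union = np.maximum(union, vh.render_segment_mask(pts[labels == s], 0.05, cam))
        assert np.array_equal(whole, union)


class TestSegmentSilhouette:
    def test_full_mask_is_identity(self):
        sil = _sil(np.arange(16).reshape(4, 4))
        out = vh.segment_silhouette(sil, np.full((4, 4), 255, dtype=np.uint8))
        assert np.array_equal(out.values, sil.values)

    def test_zero_mask_blanks(self):
        sil = _sil(np.full((4, 4), 200))
        out = vh.segment_silhouette(sil, np.zeros((4, 4), dtype=np.uint8))
        assert not out.values.any()

    def test_checkerboard(self):
        sil = _sil(np.full((4, 4), 128))
        mask = np.zeros((4, 4), dtype=np.uint8)
        mask[::2, ::2] = 255
        out = vh.segment_silhouette(sil, mask)
        assert np.all(out.values[mask == 255] == 128)
        assert np.all(out.values[mask != 255] == 0)

    def test_dimension_mismatch(self):
        with pytest.raises(InputMismatchError):
            vh.segment_silhouette(_sil(np.zeros((4, 4))), np.zeros((5, 5), dtype=np.uint8))


class TestUncertainRatio:
    def test_hand_counted_quarter(self):
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[:10, :10] = 255  # N = 100
        sil = np.zeros((10, 10), dtype=np.uint8)
        sil[:5, :5] = 128  # 25 uncertain pixels
        q = vh.uncertain_ratio(_sil(sil), mask)
        assert (q.m, q.n, q.f) == (25, 100, 0.25)

    def test_binary_silhouette_gives_zero(self):
        mask = np.full((6, 6), 255, dtype=np.uint8)
        sil = np.zeros((6, 6), dtype=np.uint8)
        sil[2:, :] = 255
        q = vh.uncertain_ratio(_sil(sil), mask)
        assert q.m == 0 and q.f == 0.0

    def test_empty_projection_raises(self):
        with pytest.raises(EmptyProjectionError):
            vh.uncertain_ratio(_sil(np.zeros((5, 5))), np.zeros((5, 5), dtype=np.uint8))

    def test_scale_free_under_tiling(self, rng):
        sil = rng.integers(0, 256, size=(8, 8), dtype=np.uint8).astype(np.uint8)
        mask = np.where(rng.random((8, 8)) < 0.6, 255, 0).astype(np.uint8)
        if not (mask == 255).any():
            mask[0, 0] = 255
        q1 = vh.uncertain_ratio(_sil(sil), mask)
        q2 = vh.uncertain_ratio(_sil(np.tile(sil, (2, 2))), np.tile(mask, (2, 2)))
        assert q2.m == 4 * q1.m and q2.n == 4 * q1.n
        assert q2.f == pytest.approx(q1.f)


class TestSelectViews:
    def _q(self, cam, f):
        return vh.SegmentViewQuality(segment_id=0, camera_id=cam, m=0, n=1, f=f)

    def test_keeps_below_threshold(self):
        cfg = vh.SegmentationConfig(f_t=0.1, min_views=1)
        kept = vh.select_views([self._q("a", 0.05), self._q("b", 0.5)], cfg)
        assert kept == ["a"]

    def test_keeps_all_when_all_pass(self):
        cfg = vh.SegmentationConfig(f_t=0.5, min_views=1)
        qs = [self._q(c, f) for c, f in [("a", 0.1), ("b", 0.2), ("c", 0.3)]]
        assert vh.select_views(qs, cfg) == ["a", "b", "c"]

    def test_fallback_keeps_lowest_f_with_warning(self):
        cfg = vh.SegmentationConfig(f_t=0.01, min_views=3)
        qs = [self._q(c, f) for c, f in [("a", 0.9), ("b", 0.3), ("c", 0.5), ("d", 0.7)]]
        with pytest.warns(UserWarning):
            kept = vh.select_views(qs, cfg)
        assert sorted(kept) == ["b", "c", "d"]
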