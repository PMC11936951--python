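"""Transform algebra, Umeyama alignment, and ICP tests."""

import numpy as np
import pytest
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

import ecgloc
from ecgloc.errors import InvalidInputError, NoOverlapError, ReconstructionError
from ecgloc.geometry import ColoredPointCloud, backproject_frame
from ecgloc.registration import (IcpConfig, RigidTransform, icp_point_to_plane,
                                 icp_point_to_point, reconstruct_torso,
                                 umeyama_align, voxel_downsample)

from conftest import surface_patch


def random_rigid(rng, max_angle=np.pi):
    rot = Rotation.from_rotvec(rng.uniform(-1, 1, 3) * max_angle).as_matrix()
    return RigidTransform(rot, rng.uniform(-100, 100, 3))


def rotation_angle(r):
    return float(np.arccos(np.clip((np.trace(r) - 1) / 2.0, -1.0, 1.0)))


class TestRigidTransform:
    def test_preserves_pairwise_distances(self):
        rng = np.random.default_rng(11)
        pts = rng.uniform(-200, 200, size=(40, 3))
        d0 = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        for _ in range(20):
            t = random_rigid(rng)
            moved = t.apply(pts)
            d1 = np.linalg.norm(moved[:, None] - moved[None, :], axis=2)
            np.testing.assert_allclose(d1, d0, rtol=1e-9, atol=1e-9)

    def test_rotation_invariants(self):
        rng = np.random.default_rng(12)
        t = random_rigid(rng)
        for _ in range(50):  # long composition chains stay orthonormal
            t = t.compose(random_rigid(rng))
        assert np.abs(t.rotation @ t.rotation.T - np.eye(3)).max() < 1e-9
        assert abs(np.linalg.det(t.rotation) - 1.0) < 1e-9

    def test_compose_inverse_is_identity(self):
        rng = np.random.default_rng(13)
        t = random_rigid(rng)
        r = t.compose(t.inverse())
        assert rotation_angle(r.rotation) < 1e-12
        assert np.linalg.norm(r.translation) < 1e-9

    def test_non_orthonormal_rejected(self):
        with pytest.raises(InvalidInputError):
            RigidTransform(np.eye(3) * 1.1, np.zeros(3))


class TestUmeyama:
    def test_identity_on_equal_sets(self):
        rng = np.random.default_rng(21)
        pts = rng.uniform(-100, 100, size=(30, 3))
        sim = umeyama_align(pts, pts)
        assert sim.scale == pytest.approx(1.0, abs=1e-12)
        assert rotation_angle(sim.rotation) < 1e-9
        assert np.linalg.norm(sim.translation) < 1e-9

    def test_recovers_constructed_similarity(self):
        rng = np.random.default_rng(22)
        src = rng.uniform(-100, 100, size=(50, 3))
        rot = Rotation.from_euler("zyx", [30, -15, 70], degrees=True).as_matrix()
        t = np.array([10.0, -4.0, 7.0])
        tgt = 2.5 * src @ rot.T + t
        sim = umeyama_align(src, tgt, with_scale=True)
        assert sim.scale == pytest.approx(2.5, rel=1e-9)
        np.testing.assert_allclose(sim.rotation, rot, atol=1e-9)
        np.testing.assert_allclose(sim.translation, t, atol=1e-7)

    def test_collinear_points_rejected(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(InvalidInputError):
            umeyama_align(pts, pts * 2.0)

    def test_length_mismatch_rejected(self):
        rng = np.random.default_rng(23)
        with pytest.raises(InvalidInputError):
            umeyama_align(rng.uniform(size=(5, 3)), rng.uniform(size=(6, 3)))

    def test_reflection_corrected_to_proper_rotation(self):
        rng = np.random.default_rng(24)
        src = rng.uniform(-50, 50, size=(40, 3))
        tgt = src.copy()
        tgt[:, 2] *= -1.0  # mirrored target: best orthogonal map is a reflection
        sim = umeyama_align(src, tgt)
        assert np.linalg.det(sim.rotation) == pytest.approx(1.0, abs=1e-9)


def make_cloud(points):
    return ColoredPointCloud(points, np.full((len(points), 3), 0.5))


class TestIcp:
    def test_fixed_point_source_equals_target(self):
        patch = surface_patch()
        for variant in (icp_point_to_point, icp_point_to_plane):
            history = []
            t = variant(patch, patch, callback=lambda i, o: history.append(o))
            assert history[0] == pytest.approx(0.0, abs=1e-9)
            assert rotation_angle(t.rotation) < 1e-9
            assert np.linalg.norm(t.translation) < 1e-9

    def test_point_to_point_recovers_pure_translation(self):
        patch = surface_patch()
        true = RigidTransform(np.eye(3), [0.0, 0.0, 3.0])
        src = true.inverse().apply(patch)
        got = icp_point_to_point(src, patch)
        err = got.compose(true.inverse())
        assert np.linalg.norm(err.translation) < 1e-2

    def test_init_at_ground_truth_stays(self):
        patch = surface_patch()
        rng = np.random.default_rng(31)
        true = random_rigid(rng, max_angle=0.3)
        src = true.inverse().apply(patch)
        got = icp_point_to_point(src, patch, init=true)
        err = got.compose(true.inverse())
        # matrix-norm comparison: arccos cannot resolve angles below ~1e-8
        assert np.abs(err.rotation - np.eye(3)).max() < 1e-9
        assert np.linalg.norm(err.translation) < 1e-6

    def test_objective_monotonically_non_increasing(self):
        patch = surface_patch()
        rot = Rotation.from_euler("z", 10, degrees=True).as_matrix()
        true = RigidTransform(rot, [5.0, 0.0, 0.0])
        src = true.inverse().apply(patch)
        for variant in (icp_point_to_plane, icp_point_to_point):
            history = []
            variant(src, patch, callback=lambda i, o: history.append(o))
            diffs = np.diff(history)
            assert np.all(diffs <= 1e-12)

    def test_no_overlap_raises(self):
        patch = surface_patch()
        cfg = IcpConfig()
        far = patch + np.array([10 * cfg.max_corr_dist_plane, 0, 0])
        with pytest.raises(NoOverlapError):
            icp_point_to_plane(far, patch, config=cfg)
        with pytest.raises(NoOverlapError):
            icp_point_to_point(far, patch, config=cfg)


class TestReconstruct:
    def test_single_cloud_passthrough(self):
        cloud = make_cloud(surface_patch(n_theta=20, n_y=15))
        merged, transforms = reconstruct_torso([cloud])
        assert len(transforms) == 1
        assert rotation_angle(transforms[0].rotation) == 0.0
        np.testing.assert_array_equal(merged.points, cloud.points)

    def test_non_overlapping_pair_aborts_with_index(self):
        patch = surface_patch(n_theta=20, n_y=15)
        far = patch + np.array([5000.0, 0.0, 0.0])
        with pytest.raises(ReconstructionError) as exc:
            reconstruct_torso([make_cloud(patch), make_cloud(far)])
        assert exc.value.pair == (0, 1)

    def test_noiseless_views_align_to_surface(self, noiseless_scene, noiseless_frames,
                                              noiseless_result):
        """Each transformed per-view cloud lies on the true torso surface."""
        p0 = noiseless_scene.path.pose(0)
        surf = noiseless_scene.surface
        for k, frame in enumerate(noiseless_frames):
            pts = noiseless_result.transforms[k].apply(
                backproject_frame(frame, stride=4).points)
            world = p0.apply(pts)
            keep = world[:, 1] < surf.y_shoulder + 0.6 * surf.dome_height
            d = surf.surface_distance(world[keep])
            assert np.sqrt(np.mean(d ** 2)) < 0.1

    def test_merged_cloud_reaches_every_electrode(self, noiseless_scene,
                                                  noiseless_frames):
        """Full-resolution reconstruction puts a point within 0.5 mm of every
        ground-truth electrode center."""
        clouds = [backproject_frame(f, stride=1) for f in noiseless_frames]
        merged, _ = reconstruct_torso(clouds)
        gt_frame0 = noiseless_scene.path.pose(0).inverse().apply(
            noiseless_scene.ground_truth.positions)
        dist, _ = cKDTree(merged.points).query(gt_frame0)
        assert dist.max() < 0.5
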