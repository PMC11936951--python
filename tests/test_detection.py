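"""Reference detector, 3D center extraction, and multi-view fusion tests."""

import numpy as np
import pytest

import ecgloc
from ecgloc.detection import (CLASS_COLORS, Detection, ElectrodeClass,
                              detect_electrodes_reference, extract_centers_3d,
                              fuse_views)
from ecgloc.errors import ConfigError, InvalidInputError
from ecgloc.geometry import CameraIntrinsics, RGBDFrame
from ecgloc.phantom import (CameraPath, PhantomLayout, StripSpec, build_phantom,
                            render_views)
from ecgloc.registration import RigidTransform


@pytest.fixture(scope="module")
def two_per_class_render():
    """One rendered view of a small scene: 2 electrodes of each class."""
    specs = tuple(
        StripSpec(cls=cls, count=2, theta_deg=theta, y_top=40.0)
        for cls, theta in zip(ElectrodeClass, (-30.0, -10.0, 10.0, 30.0))
    )
    scene = build_phantom(layout=PhantomLayout(strip_specs=specs))
    mid = scene.path.n_views // 2
    frame, dets = render_views(scene)[mid]
    return scene, frame, dets


class TestReferenceDetector:
    def test_matches_rendered_ground_truth(self, two_per_class_render):
        _, frame, gt_dets = two_per_class_render
        found = detect_electrodes_reference(frame.rgb)
        assert len(found) == 8
        assert sorted(d.cls.name for d in found) == sorted(d.cls.name for d in gt_dets)
        # each detection's box must coincide with one ground-truth box
        for det in found:
            best = min(gt_dets, key=lambda g: abs(np.asarray(g.bbox) - det.bbox).max())
            assert abs(np.asarray(best.bbox) - det.bbox).max() <= 1.0
            assert best.cls is det.cls

    def test_blank_image_yields_nothing(self):
        img = np.full((60, 80, 3), 35, dtype=np.uint8)
        assert detect_electrodes_reference(img) == []

    def test_separated_same_class_disks_stay_distinct(self):
        img = np.full((80, 120, 3), 35, dtype=np.uint8)
        color = CLASS_COLORS[ElectrodeClass.B]
        yy, xx = np.mgrid[0:80, 0:120]
        for cx in (30, 90):  # centers two diameters apart
            img[(xx - cx) ** 2 + (yy - 40) ** 2 <= 6 ** 2] = color
        found = detect_electrodes_reference(img)
        assert len(found) == 2
        assert all(d.cls is ElectrodeClass.B for d in found)


class TestExtractCenters:
    INTR = CameraIntrinsics(fx=600.0, fy=600.0, cx=39.5, cy=29.5, width=80, height=60)

    def _frame(self, depth):
        rgb = np.zeros(depth.shape + (3,), dtype=np.uint8)
        return RGBDFrame(rgb=rgb, depth=depth, intrinsics=self.INTR, view_index=0)

    def test_flat_patch_centered_on_principal_point(self):
        depth = np.full((60, 80), 500.0)
        det = Detection(bbox=(30, 20, 50, 40), cls=ElectrodeClass.A)  # centered on (cx+.5, cy+.5)
        centers, classes, dropped = extract_centers_3d([det], self._frame(depth))
        assert dropped == []
        assert classes == [ElectrodeClass.A]
        np.testing.assert_allclose(centers[0], [0.0, 0.0, 500.0], atol=1e-9)

    def test_invalid_depth_box_dropped_and_reported(self):
        depth = np.zeros((60, 80))
        det = Detection(bbox=(10, 10, 20, 20), cls=ElectrodeClass.B)
        centers, classes, dropped = extract_centers_3d([det], self._frame(depth))
        assert len(centers) == 0 and dropped == [0]

    def test_curved_phantom_centers_match_ground_truth(self, two_per_class_render):
        scene, frame, gt_dets = two_per_class_render
        centers, classes, dropped = extract_centers_3d(gt_dets, frame)
        assert dropped == []
        cam = scene.path.pose(frame.view_index).inverse().apply(
            scene.ground_truth.positions)
        for c in centers:
            assert np.min(np.linalg.norm(cam - c, axis=1)) < 1.0


def single_linkage_oracle(points, radius):
    """Brute-force union-find single linkage at a distance threshold."""
    parent = list(range(len(points)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(points)):
        for j in range(i + 1, len(points)):
            if np.linalg.norm(points[i] - points[j]) <= radius:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(len(points)):
        groups.setdefault(find(i), []).append(i)
    return sorted(sorted(g) for g in groups.values())


class TestFuseViews:
    def test_two_exact_views_fuse_to_truth(self):
        truth = np.array([[10.0, -5.0, 480.0]])
        cls = [ElectrodeClass.C]
        rng = np.random.default_rng(41)
        views, transforms = [], []
        for _ in range(2):
            t = RigidTransform(
                np.linalg.qr(rng.normal(size=(3, 3)))[0] * 1.0, rng.uniform(-50, 50, 3))
            # ensure proper rotation
            rot = t.rotation if np.linalg.det(t.rotation) > 0 else -t.rotation
            t = RigidTransform(rot, t.translation)
            views.append((t.inverse().apply(truth), cls))
            transforms.append(t)
        fused = fuse_views(views, transforms, merge_radius=14.0)
        assert len(fused) == 1
        assert fused.support[0] == 2
        np.testing.assert_allclose(fused.positions[0], truth[0], atol=1e-9)

    def test_fusion_beats_single_view_error_monte_carlo(self):
        """Averaging 12 noisy views beats the mean single-view error."""
        rng = np.random.default_rng(42)
        truth = np.array([[0.0, 0.0, 500.0]])
        cls = [ElectrodeClass.A]
        identity = RigidTransform.identity()
        fused_err, single_err = [], []
        for _ in range(100):
            noisy = [truth + rng.normal(0, 1.0, size=(1, 3)) for _ in range(12)]
            fused = fuse_views([(n, cls) for n in noisy], [identity] * 12, 14.0)
            fused_err.append(np.linalg.norm(fused.positions[0] - truth[0]))
            single_err.append(np.mean([np.linalg.norm(n - truth) for n in noisy]))
        assert np.mean(fused_err) < np.mean(single_err)

    def test_neighboring_electrodes_never_merge(self):
        pts = np.array([[0.0, 0.0, 500.0], [0.0, 30.0, 500.0]])
        cls = [ElectrodeClass.D, ElectrodeClass.D]
        fused = fuse_views([(pts, cls)], [RigidTransform.identity()], merge_radius=14.0)
        assert len(fused) == 2
        assert single_linkage_oracle(pts, 14.0) == [[0], [1]]

    def test_grouping_matches_single_linkage_oracle(self):
        rng = np.random.default_rng(43)
        base = np.array([[0.0, 0.0, 500.0], [0.0, 40.0, 500.0], [40.0, 0.0, 500.0]])
        pts = np.vstack([b + rng.normal(0, 3.0, size=(4, 3)) for b in base])
        cls = [ElectrodeClass.B] * len(pts)
        fused = fuse_views([(pts, cls)], [RigidTransform.identity()], merge_radius=14.0)
        oracle_groups = single_linkage_oracle(pts, 14.0)
        assert len(fused) == len(oracle_groups)
        oracle_means = sorted(tuple(np.round(pts[g].mean(axis=0), 9)) for g in oracle_groups)
        got_means = sorted(tuple(np.round(p, 9)) for p in fused.positions)
        assert oracle_means == got_means

    def test_view_order_invariance(self, noiseless_result, noiseless_frames,
                                   noiseless_detections):
        per_view = []
        for frame, dets in zip(noiseless_frames, noiseless_detections):
            centers, classes, _ = extract_centers_3d(dets, frame)
            per_view.append((centers, classes))
        transforms = noiseless_result.transforms
        forward = fuse_views(per_view, transforms, 14.0)
        rng = np.random.default_rng(44)
        order = rng.permutation(len(per_view))
        shuffled = fuse_views([per_view[i] for i in order],
                              [transforms[i] for i in order], 14.0)
        np.testing.assert_allclose(forward.positions, shuffled.positions, atol=1e-9)
        assert forward.classes == shuffled.classes
        np.testing.assert_array_equal(forward.support, shuffled.support)

    def test_support_conservation(self, noiseless_result, noiseless_frames,
                                  noiseless_detections):
        total_centers = 0
        per_view = []
        for frame, dets in zip(noiseless_frames, noiseless_detections):
            centers, classes, dropped = extract_centers_3d(dets, frame)
            total_centers += len(centers)
            per_view.append((centers, classes))
        fused = fuse_views(per_view, noiseless_result.transforms, 14.0)
        assert fused.support.sum() == total_centers

    def test_bad_merge_radius_rejected(self):
        with pytest.raises(ConfigError):
            fuse_views([], [], merge_radius=15.0, nominal_spacing=30.0)
        with pytest.raises(ConfigError):
            fuse_views([], [], merge_radius=0.0)
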