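"""Forearm skeleton-line detection: canonical frame, slicing, clustering,
ellipse fitting, robust line fit, and key-point placement."""

import numpy as np
import pytest

from armalign import ScanSimConfig, select_best_sensor, simulate_scan
from armalign.forearm import (
    ForearmConfig,
    canonicalize,
    cluster_slice,
    detect_forearm_keypoints,
    fit_ellipse,
    forearm_keypoints,
    initial_axis,
    ransac_line,
    slice_cloud,
)
from armalign.geometry import DegenerateGeometryError, PointCloud, apply_transform
from conftest import random_rigid_transform


def cylinder_cloud(rng, radius=30.0, zmin=-200.0, zmax=0.0, n=5000, sigma=0.0):
    theta = rng.uniform(0, 2 * np.pi, n)
    z = rng.uniform(zmin, zmax, n)
    pts = np.c_[radius * np.cos(theta), radius * np.sin(theta), z]
    if sigma > 0:
        pts += rng.normal(0, sigma, pts.shape)
    return PointCloud(pts)


class TestInitialAxis:
    def test_cylinder_axis(self, rng):
        line = initial_axis(cylinder_cloud(rng), reference_point=[0.0, 0.0, 50.0])
        angle = np.degrees(np.arccos(abs(line.direction @ [0, 0, 1])))
        assert angle < 0.5
        assert line.direction[2] > 0  # points toward the reference

    def test_full_arm_close_to_forearm_axis(self, arm_model, clean_triplet):
        sel = select_best_sensor(clean_triplet.detections)
        cloud = clean_triplet.merged()
        line = initial_axis(cloud, reference_point=sel.keypoints.barycenter())
        true_axis = clean_triplet.truth_transform.invert().rotation @ [0.0, 0.0, 1.0]
        angle = np.degrees(np.arccos(abs(line.direction @ true_axis)))
        assert angle < 5.0

    def test_rotation_equivariance(self, rng):
        cloud = cylinder_cloud(rng, n=2000)
        t = random_rigid_transform(rng)
        l0 = initial_axis(cloud)
        l1 = initial_axis(apply_transform(t, cloud))
        assert abs(l1.direction @ (t.rotation @ l0.direction)) > 1 - 1e-6


class TestCanonicalize:
    def test_axis_maps_to_z_and_barycenter_to_origin(self, rng):
        cloud = cylinder_cloud(rng)
        t = random_rigid_transform(rng)
        moved = apply_transform(t, cloud)
        bary = t.transform_points(np.array([[0.0, 0.0, 40.0]]))[0]
        canon, transform = canonicalize(moved, bary)
        from armalign import inertia_frame

        frame = inertia_frame(canon)
        assert abs(abs(frame.axes[0][2]) - 1.0) < 1e-6
        np.testing.assert_allclose(transform.transform_points(bary[None])[0], 0.0, atol=1e-9)

    def test_canonical_cloud_is_fixed_point(self, rng):
        cloud = cylinder_cloud(rng)
        canon, t1 = canonicalize(cloud, [0.0, 0.0, 30.0])
        _, t2 = canonicalize(canon, [0.0, 0.0, 0.0])
        np.testing.assert_allclose(t2.rotation, np.eye(3), atol=1e-6)


class TestSliceCloud:
    def test_plane_count(self, rng):
        cloud = cylinder_cloud(rng, zmin=-400, zmax=0, n=20000)
        ss = slice_cloud(cloud, z_start=-50.0, pitch=10.0, band=2.0, z_stop=-350.0)
        assert len(ss.heights) == 31
        np.testing.assert_allclose(ss.heights[0], -50.0)
        np.testing.assert_allclose(ss.heights[-1], -350.0)

    def test_band_membership(self, rng):
        cloud = cylinder_cloud(rng, zmin=-400, zmax=0, n=20000)
        ss = slice_cloud(cloud, -50.0, 10.0, 2.0, -350.0)
        k = list(ss.heights).index(-100.0)
        assert np.all(np.abs(ss.groups[k][:, 2] + 100.0) <= 2.0)
        radii = np.linalg.norm(ss.groups[k][:, :2], axis=1)
        np.testing.assert_allclose(radii, 30.0, atol=1e-9)

    def test_gap_yields_empty_group(self, rng):
        cloud = cylinder_cloud(rng, zmin=-150, zmax=0, n=5000)
        ss = slice_cloud(cloud, -50.0, 10.0, 2.0, -350.0, min_points=5)
        assert len(ss.groups[-1]) == 0  # below the data

    def test_no_forearm_error(self, rng):
        cloud = PointCloud(rng.normal(size=(500, 3)))  # all near origin
        with pytest.raises(DegenerateGeometryError, match="forearm not found"):
            slice_cloud(cloud, -50.0, 10.0, 2.0, -350.0)


class TestClusterSlice:
    def test_single_ring_kept_whole(self, rng):
        theta = rng.uniform(0, 2 * np.pi, 200)
        ring = np.c_[30 * np.cos(theta), 30 * np.sin(theta), np.zeros(200)]
        cluster = cluster_slice(ring, eps=10.0, min_size=10)
        assert len(cluster) == 200

    def test_detached_blob_excluded(self, rng):
        theta = rng.uniform(0, 2 * np.pi, 200)
        ring = np.c_[30 * np.cos(theta), 30 * np.sin(theta), np.zeros(200)]
        blob = rng.normal(size=(30, 3)) + [130.0, 0.0, 0.0]
        cluster = cluster_slice(np.vstack([ring, blob]), eps=10.0, min_size=10)
        assert len(cluster) == 200
        assert np.all(np.linalg.norm(cluster[:, :2], axis=1) < 40)

    def test_tie_breaks_to_previous_center(self, rng):
        a = rng.normal(0, 1.0, (50, 3)) + [0.0, 0.0, 0.0]
        b = rng.normal(0, 1.0, (50, 3)) + [100.0, 0.0, 0.0]
        cluster = cluster_slice(np.vstack([a, b]), eps=10.0, min_size=10,
                                prev_center=np.array([95.0, 0.0, 0.0]))
        assert cluster[:, 0].mean() > 50

    def test_too_small_returns_none(self, rng):
        assert cluster_slice(rng.normal(size=(5, 3)), eps=10.0, min_size=10) is None


class TestFitEllipse:
    def test_circle_center(self):
        t = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        pts = np.c_[4 + 30 * np.cos(t), -7 + 30 * np.sin(t)]
        center, fallback = fit_ellipse(pts)
        assert not fallback
        np.testing.assert_allclose(center, [4.0, -7.0], atol=1e-6)

    def test_rotated_ellipse_center(self):
        t = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        xy = np.c_[40 * np.cos(t), 25 * np.sin(t)]
        ang = np.radians(30)
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        pts = xy @ rot.T + [10.0, 5.0]
        center, fallback = fit_ellipse(pts)
        assert not fallback
        np.testing.assert_allclose(center, [10.0, 5.0], atol=1e-6)

    def test_half_arc_with_noise_median_error(self):
        errors = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            t = r.uniform(0, np.pi, 120)  # 180 degree coverage
            pts = np.c_[10 + 32 * np.cos(t), -3 + 32 * np.sin(t)]
            pts += r.normal(0, 0.3, pts.shape)
            center, _ = fit_ellipse(pts)
            errors.append(np.linalg.norm(center - [10.0, -3.0]))
        assert np.median(errors) < 1.5

    def test_few_points_fall_back_to_centroid(self, rng):
        pts = rng.normal(size=(4, 2))
        center, fallback = fit_ellipse(pts)
        assert fallback
        np.testing.assert_allclose(center, pts.mean(0))


class TestRansacLine:
    def test_collinear_all_inliers(self):
        t = np.linspace(0, 100, 12)
        centers = np.outer(t, [0.2, 0.1, 1.0]) + [5.0, -2.0, 0.0]
        line = ransac_line(centers, inlier_tol=2.0, seed=0)
        assert np.max(line.distance(centers)) < 1e-9

    def test_outliers_rejected(self):
        t = np.linspace(0, 160, 8)
        centers = np.outer(t, [0.0, 0.0, 1.0])
        centers = np.vstack([centers, [[60.0, 40.0, 50.0], [-70.0, 30.0, 120.0]]])
        line = ransac_line(centers, inlier_tol=2.0, n_iter=300, seed=1)
        # oracle: least squares on the true inliers
        angle = np.arccos(np.clip(abs(line.direction @ [0, 0, 1]), -1, 1))
        assert angle < 1e-3
        assert np.max(line.distance(centers[:8])) < 1e-6

    def test_deterministic_given_seed(self, rng):
        centers = rng.normal(size=(15, 3)) * [2.0, 2.0, 60.0]
        a = ransac_line(centers, 3.0, 200, seed=7)
        b = ransac_line(centers, 3.0, 200, seed=7)
        np.testing.assert_array_equal(a.point, b.point)
        np.testing.assert_array_equal(a.direction, b.direction)

    def test_too_few_centers(self):
        with pytest.raises(ValueError):
            ransac_line(np.zeros((1, 3)), 2.0)


class TestForearmKeypoints:
    def test_default_heights_on_z_axis(self):
        from armalign.forearm import SkeletonLine

        line = SkeletonLine([0.0, 0.0, 0.0], [0.0, 0.0, 1.0])
        fkp = forearm_keypoints(line, [0.0, 0.0, 0.0], [-200.0, -250.0, -300.0, -350.0])
        np.testing.assert_allclose(
            fkp.points,
            [[0, 0, -200], [0, 0, -250], [0, 0, -300], [0, 0, -350.0]],
            atol=1e-12,
        )

    def test_oblique_line_parametrization(self):
        from armalign.forearm import SkeletonLine

        line = SkeletonLine([1.0, 1.0, 0.0], [0.0, 0.0, 1.0])
        fkp = forearm_keypoints(line, [1.0, 1.0, 50.0], [-200.0])
        np.testing.assert_allclose(fkp.points[0], [1.0, 1.0, -150.0], atol=1e-9)

    def test_points_lie_on_line(self, rng):
        from armalign.forearm import SkeletonLine

        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        line = SkeletonLine(rng.normal(size=3) * 10, d)
        fkp = forearm_keypoints(line, rng.normal(size=3) * 20, [-200.0, -250.0])
        for p in fkp.points:
            assert np.linalg.norm(np.cross(p - line.point, line.direction)) < 1e-6


class TestEndToEndDetection:
    def _axis_metrics(self, triplet, cfg=None):
        sel = select_best_sensor(triplet.detections)
        fkp, line, _ = detect_forearm_keypoints(
            triplet.merged(), sel.keypoints.barycenter(), cfg
        )
        w = triplet.truth_transform
        dir_w = w.transform_directions(line.direction[None])[0]
        angle = np.degrees(np.arccos(abs(dir_w[2])))
        pts_w = w.transform_points(fkp.points)
        axis_dist = np.linalg.norm(pts_w[:, :2], axis=1).max()
        return angle, axis_dist

    def test_noiseless_arm_axis_and_fkps(self, clean_triplet):
        angle, axis_dist = self._axis_metrics(clean_triplet)
        assert angle < 1.0
        assert axis_dist < 2.0

    def test_equivariance_under_rigid_motion(self, arm_model, clean_triplet, rng):
        sel = select_best_sensor(clean_triplet.detections)
        cloud = clean_triplet.merged()
        bary = sel.keypoints.barycenter()
        fkp0, _, _ = detect_forearm_keypoints(cloud, bary)
        t = random_rigid_transform(rng)
        fkp1, _, _ = detect_forearm_keypoints(
            apply_transform(t, cloud), t.transform_points(bary[None])[0]
        )
        np.testing.assert_allclose(
            fkp1.points, t.transform_points(fkp0.points), atol=1e-3
        )

    def test_noisy_arm_median_accuracy(self, arm_model):
        angles, dists = [], []
        for seed in range(15):
            cfg = ScanSimConfig(
                noise_sigma=1.0, outlier_fraction=0.02, keypoint_dropout_prob=0.0,
                n_points_per_sensor=4000, seed=200 + seed,
            )
            t = simulate_scan(arm_model, seed % 6, cfg)
            a, d = self._axis_metrics(t)
            angles.append(a)
            dists.append(d)
        assert np.median(angles) < 3.0
        assert np.median(dists) < 4.0
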