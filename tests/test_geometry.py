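"""Core geometric operators: transforms, inertia frames, normals,
downsampling, outlier filtering and the weighted absolute-orientation solver."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from armalign import (
    DegenerateGeometryError,
    PointCloud,
    RigidTransform,
    apply_transform,
    estimate_normals,
    horn_weighted_orientation,
    inertia_frame,
    sor_filter,
    voxel_downsample,
)
from conftest import random_rigid_transform


def kabsch(src, dst, weights=None):
    """Independent SVD-based superposition oracle (Kabsch algorithm)."""
    w = np.ones(len(src)) if weights is None else np.asarray(weights, float)
    cs = (w[:, None] * src).sum(0) / w.sum()
    cd = (w[:, None] * dst).sum(0) / w.sum()
    h = (w[:, None] * (src - cs)).T @ (dst - cd)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, cd - rot @ cs


class TestRigidTransform:
    def test_identity_leaves_cloud_unchanged(self, rng):
        cloud = PointCloud(rng.normal(size=(50, 3)))
        out = apply_transform(RigidTransform.identity(), cloud)
        np.testing.assert_array_equal(out.points, cloud.points)

    def test_quarter_turn_about_z(self):
        rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        out = apply_transform(RigidTransform(rot, np.zeros(3)), PointCloud([[1.0, 0.0, 0.0]]))
        np.testing.assert_allclose(out.points[0], [0.0, 1.0, 0.0], atol=1e-12)

    def test_inverse_round_trip(self, rng):
        cloud = PointCloud(rng.normal(size=(100, 3), scale=40))
        t = random_rigid_transform(rng)
        back = apply_transform(t.invert(), apply_transform(t, cloud))
        np.testing.assert_allclose(back.points, cloud.points, atol=1e-9)

    def test_preserves_pairwise_distances(self, rng):
        pts = rng.normal(size=(40, 3), scale=30)
        t = random_rigid_transform(rng)
        d0 = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        moved = t.transform_points(pts)
        d1 = np.linalg.norm(moved[:, None] - moved[None], axis=-1)
        np.testing.assert_allclose(d1, d0, rtol=1e-9, atol=1e-9)

    def test_rotation_validation(self):
        with pytest.raises(ValueError):
            RigidTransform(np.eye(3) * 2.0, np.zeros(3))

    def test_normals_rotate_with_points(self, rng):
        n = rng.normal(size=(20, 3))
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        cloud = PointCloud(rng.normal(size=(20, 3)), n)
        t = random_rigid_transform(rng)
        out = apply_transform(t, cloud)
        np.testing.assert_allclose(out.normals, n @ t.rotation.T, atol=1e-12)

    def test_empty_cloud_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            apply_transform(RigidTransform.identity(), PointCloud(np.empty((0, 3))))


class TestInertiaFrame:
    def test_segment_gives_z_axis(self, rng):
        z = np.linspace(-100, 100, 500)
        pts = np.c_[rng.normal(0, 0.5, 500), rng.normal(0, 0.2, 500), z]
        frame = inertia_frame(PointCloud(pts))
        assert abs(frame.axes[0] @ [0, 0, 1]) > 0.9999

    def test_anisotropic_gaussian_axis_order(self, rng):
        pts = rng.normal(size=(10000, 3)) * [10.0, 2.0, 1.0]
        frame = inertia_frame(PointCloud(pts))
        angle = np.degrees(np.arccos(abs(frame.axes[0] @ [1, 0, 0])))
        assert angle < 2.0
        # right-handed orthonormal basis
        np.testing.assert_allclose(frame.axes @ frame.axes.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(frame.axes) > 0.999

    def test_translation_equivariance(self, rng):
        pts = rng.normal(size=(300, 3)) * [5.0, 2.0, 1.0]
        f0 = inertia_frame(PointCloud(pts))
        f1 = inertia_frame(PointCloud(pts + [5.0, 5.0, 5.0]))
        np.testing.assert_allclose(f1.origin, f0.origin + 5.0, atol=1e-9)
        np.testing.assert_allclose(f1.axes, f0.axes, atol=1e-9)

    def test_reference_point_fixes_sign(self, rng):
        pts = np.c_[np.linspace(-50, 50, 200), rng.normal(0, 1, 200), rng.normal(0, 0.5, 200)]
        frame = inertia_frame(PointCloud(pts), reference_point=[60.0, 0.0, 0.0])
        assert frame.axes[0] @ [1, 0, 0] > 0
        frame = inertia_frame(PointCloud(pts), reference_point=[-60.0, 0.0, 0.0])
        assert frame.axes[0] @ [1, 0, 0] < 0

    def test_collinear_points_degenerate(self):
        pts = np.outer(np.linspace(0, 1, 50), [1.0, 2.0, 3.0])
        with pytest.raises(DegenerateGeometryError, match="degenerate"):
            inertia_frame(PointCloud(pts))


class TestEstimateNormals:
    def test_plane_normals(self, rng):
        pts = np.c_[rng.uniform(-50, 50, (400, 2)), np.zeros(400)]
        out = estimate_normals(PointCloud(pts), k=10)
        assert np.all(np.abs(out.normals[:, 2]) > 1 - 1e-9)

    def test_cylinder_radial_normals(self, rng):
        theta = rng.uniform(0, 2 * np.pi, 4000)
        z = rng.uniform(-100, 100, 4000)
        pts = np.c_[30 * np.cos(theta), 30 * np.sin(theta), z]
        out = estimate_normals(PointCloud(pts), k=30)
        radial = np.c_[np.cos(theta), np.sin(theta), np.zeros(4000)]
        interior = np.abs(z) < 80
        cosines = np.einsum("ij,ij->i", out.normals[interior], radial[interior])
        angles = np.degrees(np.arccos(np.clip(cosines, -1, 1)))
        assert np.percentile(angles, 99) < 5.0

    def test_unit_length(self, rng):
        out = estimate_normals(PointCloud(rng.normal(size=(200, 3), scale=20)), k=8)
        np.testing.assert_allclose(np.linalg.norm(out.normals, axis=1), 1.0, atol=1e-6)

    def test_k_too_small(self, rng):
        with pytest.raises(ValueError, match="k too small"):
            estimate_normals(PointCloud(rng.normal(size=(50, 3))), k=2)


class TestVoxelDownsample:
    def test_single_cell_collapses_to_centroid(self, rng):
        pts = rng.uniform(0, 0.5, (20, 3))
        out = voxel_downsample(PointCloud(pts), voxel=1.0)
        assert len(out) == 1
        np.testing.assert_allclose(out.points[0], pts.mean(0), atol=1e-12)

    @pytest.mark.parametrize("voxel", [0.75, 1.3, 2.5])
    def test_count_matches_brute_force_binning(self, rng, voxel):
        pts = rng.uniform(-20, 20, (3000, 3))
        out = voxel_downsample(PointCloud(pts), voxel=voxel)
        keys = np.floor((pts - pts.min(0)) / voxel).astype(int)
        n_cells = len({tuple(k) for k in keys})
        assert len(out) == n_cells

    def test_regular_grid(self):
        g = np.arange(0, 10, 1.0)
        pts = np.array(np.meshgrid(g, g, g)).reshape(3, -1).T
        out = voxel_downsample(PointCloud(pts), voxel=0.75)
        keys = np.floor((pts - pts.min(0)) / 0.75).astype(int)
        assert len(out) == len({tuple(k) for k in keys})

    def test_invalid_voxel(self, rng):
        with pytest.raises(ValueError):
            voxel_downsample(PointCloud(rng.normal(size=(10, 3))), voxel=0.0)

    def test_normals_renormalized(self, rng):
        n = rng.normal(size=(100, 3))
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        out = voxel_downsample(PointCloud(rng.uniform(0, 10, (100, 3)), n), voxel=2.0)
        np.testing.assert_allclose(np.linalg.norm(out.normals, axis=1), 1.0, atol=1e-9)


class TestSorFilter:
    def test_homogeneous_cloud_untouched(self):
        # closed surface lattice (no boundary) -> identical kNN statistics
        u = np.linspace(0, 2 * np.pi, 60, endpoint=False)
        v = np.linspace(0, 2 * np.pi, 30, endpoint=False)
        uu, vv = np.meshgrid(u, v)
        pts = np.c_[
            (40 + 15 * np.cos(vv.ravel())) * np.cos(uu.ravel()),
            (40 + 15 * np.cos(vv.ravel())) * np.sin(uu.ravel()),
            15 * np.sin(vv.ravel()),
        ]
        kept, removed = sor_filter(PointCloud(pts), k=10, std_ratio=3.0)
        assert removed.size == 0
        assert len(kept) == len(pts)

    def test_single_far_point_removed(self):
        g = np.arange(0, 8, 1.0)
        pts = np.array(np.meshgrid(g, g, g)).reshape(3, -1).T
        pts = np.vstack([pts, [[50.0, 50.0, 50.0]]])
        kept, removed = sor_filter(PointCloud(pts), k=10, std_ratio=2.0)
        # oracle: direct mean-kNN computation
        d = np.sort(np.linalg.norm(pts[:, None] - pts[None], axis=-1), axis=1)
        mean_knn = d[:, 1:11].mean(1)
        expected = np.flatnonzero(mean_knn > mean_knn.mean() + 2.0 * mean_knn.std())
        np.testing.assert_array_equal(removed, expected)
        assert list(removed) == [len(pts) - 1]

    def test_removes_injected_gross_outliers(self, arm_model, rng):
        pts, _ = arm_model.sample_surface(4000, rng)
        n_out = 200  # 5% gross outliers, guaranteed far from the whole surface
        idx = rng.choice(len(pts), n_out, replace=False)
        pts = pts.copy()
        for i in idx:
            while True:
                d = rng.normal(size=3)
                cand = pts[i] + rng.uniform(60.0, 140.0) * d / np.linalg.norm(d)
                if arm_model.surface_distance(cand[None])[0] >= 30.0:
                    pts[i] = cand
                    break
        _, removed = sor_filter(PointCloud(pts), k=20, std_ratio=2.0)
        recall = len(set(idx) & set(removed)) / n_out
        assert recall >= 0.9

    def test_k_too_large(self, rng):
        with pytest.raises(ValueError):
            sor_filter(PointCloud(rng.normal(size=(10, 3))), k=10)


class TestHornOrientation:
    def test_identity_on_identical_sets(self, rng):
        pts = rng.normal(size=(10, 3), scale=20)
        t = horn_weighted_orientation(pts, pts)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(t.translation, 0.0, atol=1e-9)

    def test_recovers_known_transform(self):
        src = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10.0]])
        rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        dst = src @ rot.T + [1.0, 2.0, 3.0]
        t = horn_weighted_orientation(src, dst)
        np.testing.assert_allclose(t.transform_points(src), dst, atol=1e-9)

    def test_zero_weight_pair_ignored(self, rng):
        src = rng.normal(size=(8, 3), scale=15)
        t_true = random_rigid_transform(rng)
        dst = t_true.transform_points(src)
        dst_broken = dst.copy()
        dst_broken[3] += [100.0, -50.0, 25.0]
        w = np.ones(8)
        w[3] = 0.0
        t_w = horn_weighted_orientation(src, dst_broken, w)
        t_ref = horn_weighted_orientation(np.delete(src, 3, 0), np.delete(dst, 3, 0))
        np.testing.assert_allclose(t_w.matrix, t_ref.matrix, atol=1e-9)

    def test_agrees_with_kabsch_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 51))
            src = rng.normal(size=(n, 3), scale=30)
            t_true = random_rigid_transform(rng)
            dst = t_true.transform_points(src) + rng.normal(0, 0.5, (n, 3))
            t = horn_weighted_orientation(src, dst)
            rot_k, tr_k = kabsch(src, dst)
            rms = np.sqrt(
                ((t.transform_points(src) - (src @ rot_k.T + tr_k)) ** 2).sum(1).mean()
            )
            assert rms < 1e-8

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="insufficient"):
            horn_weighted_orientation([[0, 0, 0], [1, 1, 1.0]], [[0, 0, 0], [1, 1, 1.0]])

    def test_collinear_degenerate(self):
        src = np.outer(np.arange(5.0), [1.0, 1.0, 0.0])
        with pytest.raises(ValueError, match="degenerate"):
            horn_weighted_orientation(src, src)
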