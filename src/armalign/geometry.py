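"""Foundational geometric types and operators for limb-scan registration.

All coordinates are in millimetres. A :class:`PointCloud` is the object being
registered; a :class:`RigidTransform` is a proper rotation plus translation
mapping a moving cloud into a fixed frame. The module also provides the
neighborhood operators every later stage relies on: principal-inertia frames,
kNN normal estimation, voxel-grid downsampling, statistical outlier removal
(SOR), and Horn's quaternion-based weighted absolute-orientation solver used
by the coarse registration stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "PointCloud",
    "RigidTransform",
    "InertiaFrame",
    "CameraIntrinsics",
    "DegenerateGeometryError",
    "apply_transform",
    "inertia_frame",
    "estimate_normals",
    "voxel_downsample",
    "sor_filter",
    "horn_weighted_orientation",
]


class DegenerateGeometryError(ValueError):
    """Raised when a geometric operation receives degenerate input."""


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"points must be (N, 3), got {pts.shape}")
    return pts


@dataclass
class PointCloud:
    """N x 3 point coordinates (mm) with optional unit normals and labels.

    Parameters
    ----------
    points : (N, 3) array
        Cartesian coordinates in millimetres; must be finite.
    normals : (N, 3) array, optional
        Unit outward normals, one per point.
    labels : (N,) int array, optional
        Per-point integer tags (e.g. sensor id or pose id).
    """

    points: np.ndarray
    normals: np.ndarray | None = None
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = _as_points(self.points)
        if not np.isfinite(self.points).all():
            raise ValueError("point coordinates must be finite")
        if self.normals is not None:
            self.normals = _as_points(self.normals)
            if len(self.normals) != len(self.points):
                raise ValueError("normals count must equal point count")
            norms = np.linalg.norm(self.normals, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise ValueError("normals must be unit length (within 1e-6)")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if len(self.labels) != len(self.points):
                raise ValueError("labels count must equal point count")

    def __len__(self) -> int:
        return len(self.points)

    def select(self, index) -> "PointCloud":
        """Subset the cloud by an index array or boolean mask."""
        return PointCloud(
            self.points[index],
            None if self.normals is None else self.normals[index],
            None if self.labels is None else self.labels[index],
        )


def concatenate(clouds) -> PointCloud:
    """Stack several clouds; normals/labels kept only if present on all."""
    clouds = list(clouds)
    pts = np.vstack([c.points for c in clouds])
    normals = None
    if all(c.normals is not None for c in clouds):
        normals = np.vstack([c.normals for c in clouds])
    labels = None
    if all(c.labels is not None for c in clouds):
        labels = np.concatenate([c.labels for c in clouds])
    return PointCloud(pts, normals, labels)


@dataclass
class RigidTransform:
    """Proper rigid motion p -> R p + t (rotation matrix R, translation t in mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        det = np.linalg.det(self.rotation)
        if err > 1e-6 or abs(det - 1.0) > 1e-6:
            raise ValueError("rotation must be orthonormal with determinant +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @property
    def matrix(self) -> np.ndarray:
        """4 x 4 homogeneous matrix (row-major)."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m) -> "RigidTransform":
        m = np.asarray(m, dtype=float).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then self."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def invert(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def transform_points(self, points: np.ndarray) -> np.ndarray:
        return _as_points(points) @ self.rotation.T + self.translation

    def transform_directions(self, dirs: np.ndarray) -> np.ndarray:
        return _as_points(dirs) @ self.rotation.T


@dataclass
class InertiaFrame:
    """Centroid plus right-handed orthonormal axes ordered by ascending moment of inertia.

    ``axes[0]`` is the direction of lowest moment of inertia, i.e. the direction
    of largest spatial spread (a limb's longitudinal axis); ``axes[1]`` is the
    intermediate direction.
    """

    origin: np.ndarray
    axes: np.ndarray  # rows are the axes

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)


@dataclass
class CameraIntrinsics:
    """Pinhole camera model (focal lengths and principal point in pixels)."""

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point must lie inside the image")


def apply_transform(transform: RigidTransform, cloud: PointCloud) -> PointCloud:
    """Apply a rigid transform to a cloud: p -> R p + t, n -> R n; labels preserved."""
    if len(cloud) == 0:
        raise ValueError("empty input")
    return PointCloud(
        transform.transform_points(cloud.points),
        None if cloud.normals is None else transform.transform_directions(cloud.normals),
        cloud.labels,
    )


def _oriented(axis: np.ndarray, centered: np.ndarray, reference: np.ndarray | None) -> np.ndarray:
    """Fix the sign of ``axis`` deterministically.

    If a reference point offset is given, the reference gets a positive
    coordinate; otherwise the point farthest from the centroid does.
    """
    if reference is not None and abs(float(reference @ axis)) > 1e-9:
        return axis if float(reference @ axis) > 0 else -axis
    far = centered[np.argmax(np.einsum("ij,ij->i", centered, centered))]
    return axis if float(far @ axis) >= 0 else -axis


def inertia_frame(cloud: PointCloud, reference_point: np.ndarray | None = None) -> InertiaFrame:
    """Principal-inertia frame of a cloud.

    The moment of inertia about a unit axis u is tr(C) - u' C u with C the
    point covariance, so the *lowest* moment corresponds to the covariance
    eigenvector of *largest* eigenvalue: the direction the cloud is most
    elongated along. Axes are returned in ascending-moment order.

    Sign convention: ``axes[0]`` points so that ``reference_point`` (when
    given, e.g. the hand-keypoint barycenter) has a positive coordinate;
    without one, the point farthest from the centroid does. ``axes[1]`` is
    oriented by the sign of the third moment (skewness) of the projections,
    falling back to the farthest-point rule when the skew is negligible;
    ``axes[2]`` completes a right-handed basis.
    """
    pts = cloud.points
    if len(pts) < 3:
        raise DegenerateGeometryError("degenerate inertia: need at least 3 points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    cov = centered.T @ centered / len(pts)
    evals, evecs = np.linalg.eigh(cov)  # ascending eigenvalues
    order = np.argsort(evals)[::-1]  # descending variance = ascending inertia
    evals = evals[order]
    evecs = evecs[:, order]
    if evals[1] <= 1e-12 * max(evals[0], 1.0):
        raise DegenerateGeometryError("degenerate inertia: points are collinear or coincident")
    ref = None if reference_point is None else np.asarray(reference_point, float) - centroid
    a0 = _oriented(evecs[:, 0], centered, ref)
    proj1 = centered @ evecs[:, 1]
    skew = float(np.mean(proj1**3))
    if abs(skew) > 1e-6 * max(float(np.mean(proj1**2)) ** 1.5, 1e-12):
        a1 = evecs[:, 1] if skew > 0 else -evecs[:, 1]
    else:
        a1 = _oriented(evecs[:, 1], centered, None)
    a2 = np.cross(a0, a1)
    return InertiaFrame(centroid, np.vstack([a0, a1, a2]))


def estimate_normals(
    cloud: PointCloud,
    k: int = 30,
    orient_axis: "tuple[np.ndarray, np.ndarray] | None" = None,
    sensor_origin: np.ndarray | None = None,
) -> PointCloud:
    """Estimate unit normals from the smallest eigenvector of each kNN covariance.

    Orientation: toward ``sensor_origin`` when given; otherwise radially away
    from ``orient_axis`` (a ``(point, direction)`` line — by default the
    cloud's own lowest-inertia axis), which approximates "exterior" on the
    quasi-tubular limb surfaces this package targets.
    """
    if k < 3:
        raise ValueError("k too small: need k >= 3")
    pts = cloud.points
    if len(pts) < k + 1:
        raise ValueError("cloud must have at least k+1 points")
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=k + 1)
    neigh = pts[idx]  # (N, k+1, 3)
    centered = neigh - neigh.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered)
    _, vecs = np.linalg.eigh(cov)
    normals = vecs[:, :, 0]  # smallest-eigenvalue eigenvector

    if sensor_origin is not None:
        outward = np.asarray(sensor_origin, float) - pts
    else:
        if orient_axis is None:
            frame = inertia_frame(cloud)
            line_pt, line_dir = frame.origin, frame.axes[0]
        else:
            line_pt = np.asarray(orient_axis[0], float)
            line_dir = np.asarray(orient_axis[1], float)
            line_dir = line_dir / np.linalg.norm(line_dir)
        rel = pts - line_pt
        outward = rel - np.outer(rel @ line_dir, line_dir)
        # on-axis points (e.g. fingertips): fall back to offset from centroid
        weak = np.linalg.norm(outward, axis=1) < 1e-9
        if weak.any():
            outward[weak] = pts[weak] - pts.mean(axis=0)
    flip = np.einsum("ij,ij->i", normals, outward) < 0
    normals[flip] *= -1
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return PointCloud(pts.copy(), normals, cloud.labels)


def voxel_downsample(cloud: PointCloud, voxel: float) -> PointCloud:
    """One point per occupied voxel, at the centroid of the voxel's members.

    Normals are averaged and renormalized; a degenerate average falls back to
    the normal of the member nearest the centroid. Labels take the nearest
    member's label.
    """
    if voxel <= 0:
        raise ValueError("voxel size must be positive")
    pts = cloud.points
    if len(pts) == 0:
        raise ValueError("empty input")
    keys = np.floor((pts - pts.min(axis=0)) / voxel).astype(np.int64)
    _, inverse, counts = np.unique(keys, axis=0, return_inverse=True, return_counts=True)
    n_cells = len(counts)
    centroids = np.zeros((n_cells, 3))
    np.add.at(centroids, inverse, pts)
    centroids /= counts[:, None]

    normals = None
    need_nearest = cloud.normals is not None or cloud.labels is not None
    nearest = None
    if need_nearest:
        d2 = np.einsum("ij,ij->i", pts - centroids[inverse], pts - centroids[inverse])
        order = np.lexsort((d2, inverse))
        first = np.searchsorted(inverse[order], np.arange(n_cells))
        nearest = order[first]
    if cloud.normals is not None:
        avg = np.zeros((n_cells, 3))
        np.add.at(avg, inverse, cloud.normals)
        norms = np.linalg.norm(avg, axis=1)
        bad = norms < 1e-9
        avg[bad] = cloud.normals[nearest[bad]]
        normals = avg / np.linalg.norm(avg, axis=1, keepdims=True)
    labels = None if cloud.labels is None else cloud.labels[nearest]
    return PointCloud(centroids, normals, labels)


def sor_filter(cloud: PointCloud, k: int = 20, std_ratio: float = 2.0):
    """Statistical outlier removal (single pass).

    Removes points whose mean distance to their k nearest neighbors exceeds
    the global mean plus ``std_ratio`` standard deviations of that statistic.

    Returns
    -------
    (PointCloud, ndarray)
        The kept cloud and the indices of removed points.
    """
    pts = cloud.points
    if len(pts) <= k:
        raise ValueError("cloud must have more than k points")
    tree = cKDTree(pts)
    dists, _ = tree.query(pts, k=k + 1)
    mean_knn = dists[:, 1:].mean(axis=1)
    thresh = mean_knn.mean() + std_ratio * mean_knn.std()
    removed = np.flatnonzero(mean_knn > thresh)
    kept = np.flatnonzero(mean_knn <= thresh)
    return cloud.select(kept), removed


def horn_weighted_orientation(src, dst, weights=None) -> RigidTransform:
    """Weighted absolute orientation by Horn's quaternion method.

    Finds the rigid transform (R, t) minimizing sum_i w_i ||R src_i + t - dst_i||^2.
    The rotation comes from the dominant eigenvector of Horn's symmetric 4x4
    quaternion matrix built from the weighted cross-covariance of the centered
    point sets.
    """
    src = _as_points(src)
    dst = _as_points(dst)
    if len(src) != len(dst):
        raise ValueError("src and dst must have equal length")
    if weights is None:
        weights = np.ones(len(src))
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    active = w > 0
    if active.sum() < 3:
        raise ValueError("insufficient correspondences: need >= 3 weighted pairs")
    wsum = w.sum()
    cs = (w[:, None] * src).sum(axis=0) / wsum
    cd = (w[:, None] * dst).sum(axis=0) / wsum
    a = src - cs
    b = dst - cd
    # degenerate when the weighted source points are (nearly) collinear
    cov_src = (w[:, None] * a).T @ a / wsum
    ev = np.linalg.eigvalsh(cov_src)
    if ev[1] <= 1e-12 * max(ev[2], 1.0):
        raise ValueError("degenerate configuration: points are collinear")

    m = (w[:, None] * a).T @ b  # weighted cross-covariance sum
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    n = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    evals, evecs = np.linalg.eigh(n)
    q = evecs[:, np.argmax(evals)]  # unit quaternion (w, x, y, z)
    qw, qx, qy, qz = q
    rot = np.array(
        [
            [1 - 2 * (qy**2 + qz**2), 2 * (qx * qy - qw * qz), 2 * (qx * qz + qw * qy)],
            [2 * (qx * qy + qw * qz), 1 - 2 * (qx**2 + qz**2), 2 * (qy * qz - qw * qx)],
            [2 * (qx * qz - qw * qy), 2 * (qy * qz + qw * qx), 1 - 2 * (qx**2 + qy**2)],
        ]
    )
    t = cd - rot @ cs
    return RigidTransform(rot, t)
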