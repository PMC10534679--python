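"""Forearm skeleton-line and key-point detection from a pose's merged cloud.

The forearm is quasi-cylindrical, so its longitudinal axis is the direction
of lowest moment of inertia. A first-attempt axis from the inertia frame is
refined by slicing the cloud with planes perpendicular to that axis below the
hand-landmark barycenter, clustering each slice, fitting an ellipse to the
retained cluster, and RANSAC-fitting a 3D line through the ellipse centers.
Forearm key points (FKPs) are then placed on the refined line at fixed
signed heights below the barycenter, giving landmarks that correspond across
scanner poses by construction (same height = same FKP index).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import DBSCAN

from .geometry import (
    DegenerateGeometryError,
    PointCloud,
    RigidTransform,
    apply_transform,
    inertia_frame,
)

__all__ = [
    "SkeletonLine",
    "SliceSet",
    "ForearmKeyPoints",
    "ForearmConfig",
    "initial_axis",
    "canonicalize",
    "slice_cloud",
    "cluster_slice",
    "fit_ellipse",
    "ransac_line",
    "forearm_keypoints",
    "detect_forearm_keypoints",
]


@dataclass
class SkeletonLine:
    """A 3D line: a point on it plus a unit direction."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float).reshape(3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3)
        n = np.linalg.norm(self.direction)
        if abs(n - 1.0) > 1e-9:
            self.direction = self.direction / n

    def distance(self, points: np.ndarray) -> np.ndarray:
        rel = np.atleast_2d(points) - self.point
        along = rel @ self.direction
        return np.linalg.norm(rel - np.outer(along, self.direction), axis=1)


@dataclass
class SliceSet:
    """Cross-section slices: plane heights, per-plane point groups, ellipse centers."""

    heights: np.ndarray  # strictly decreasing
    groups: list  # per-plane (n_k, 3) arrays (may be empty)
    centers: np.ndarray | None = None  # (m, 3) filled after clustering + ellipse fits


@dataclass
class ForearmKeyPoints:
    """Landmarks on the refined skeleton line at signed heights from the barycenter."""

    heights: np.ndarray
    points: np.ndarray

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)


@dataclass
class ForearmConfig:
    """Tunables of the forearm detector (all lengths in mm).

    Slicing runs from ``z_start`` down to ``z_stop`` below the hand-landmark
    barycenter with the given pitch, collecting points within ``band`` of each
    plane. FKP heights default to -200:-50:-350 mm below the barycenter.
    """

    z_start: float = -50.0
    pitch: float = 10.0
    band: float = 2.0
    z_stop: float = -350.0
    min_slice_points: int = 10
    cluster_eps: float = 30.0
    cluster_min_size: int = 10
    ransac_tol: float = 3.0
    ransac_iter: int = 500
    ransac_seed: int = 0
    fkp_heights: tuple = (-200.0, -250.0, -300.0, -350.0)
    min_cloud_points: int = 100


def initial_axis(cloud: PointCloud, reference_point: np.ndarray | None = None) -> SkeletonLine:
    """First-attempt skeleton line: lowest-inertia axis through the centroid.

    When ``reference_point`` (the hand-landmark barycenter) is given, the
    direction points so the reference has positive height.
    """
    frame = inertia_frame(cloud, reference_point=reference_point)
    return SkeletonLine(frame.origin, frame.axes[0])


def canonicalize(cloud: PointCloud, hand_barycenter) -> tuple:
    """Rigidly move the cloud so the initial axis is +z and the barycenter the origin.

    Returns the transformed cloud and the transform used (to map results back).
    """
    b = np.asarray(hand_barycenter, dtype=float).reshape(3)
    frame = inertia_frame(cloud, reference_point=b)
    a0, a1 = frame.axes[0], frame.axes[1]
    rot = np.vstack([a1, np.cross(a0, a1), a0])  # rows x', y', z'
    transform = RigidTransform(rot, -rot @ b)
    return apply_transform(transform, cloud), transform


def slice_cloud(
    canonical: PointCloud,
    z_start: float = -50.0,
    pitch: float = 10.0,
    band: float = 2.0,
    z_stop: float = -350.0,
    min_points: int = 10,
) -> SliceSet:
    """Collect point bands around planes z = z_start - k * pitch down to z_stop."""
    if z_start <= z_stop:
        raise ValueError("z_start must be above z_stop")
    if pitch <= 0 or band <= 0:
        raise ValueError("pitch and band must be positive")
    n_planes = int(np.floor((z_start - z_stop) / pitch)) + 1
    heights = z_start - pitch * np.arange(n_planes)
    z = canonical.points[:, 2]
    groups = [canonical.points[np.abs(z - zk) <= band] for zk in heights]
    if not any(len(g) >= min_points for g in groups):
        raise DegenerateGeometryError("forearm not found: no slice has enough points")
    return SliceSet(heights, groups)


def cluster_slice(
    slice_points: np.ndarray,
    eps: float = 30.0,
    min_size: int = 10,
    prev_center: np.ndarray | None = None,
) -> np.ndarray | None:
    """Largest Euclidean-connectivity cluster of a slice, or ``None``.

    DBSCAN with ``min_samples=1`` gives exactly the single-linkage connected
    components at linkage distance ``eps``. Size ties break to the cluster
    whose centroid is nearest ``prev_center`` (the previous plane's center).
    """
    pts = np.atleast_2d(slice_points)
    if len(pts) == 0:
        return None
    labels = DBSCAN(eps=eps, min_samples=1).fit(pts).labels_
    uniq, counts = np.unique(labels, return_counts=True)
    best = counts.max()
    if best < min_size:
        return None
    tied = uniq[counts == best]
    if len(tied) > 1 and prev_center is not None:
        cents = np.array([pts[labels == lbl].mean(axis=0) for lbl in tied])
        tied = tied[np.argsort(np.linalg.norm(cents - prev_center, axis=1), kind="stable")]
    return pts[labels == tied[0]]


def _ellipse_center(xy: np.ndarray):
    """Direct least-squares ellipse-constrained conic fit; None if it fails."""
    from skimage.measure import EllipseModel

    try:
        model = EllipseModel.from_estimate(xy)
        center = np.asarray(model.center, dtype=float)
    except Exception:
        try:  # older scikit-image API
            model = EllipseModel()
            if not model.estimate(xy):
                return None
            center = np.asarray(model.params[:2], dtype=float)
        except Exception:
            return None
    if not np.all(np.isfinite(center)):
        return None
    # reject wildly extrapolated fits (center far outside the data)
    span = np.ptp(xy, axis=0).max() + 1e-9
    if np.linalg.norm(center - xy.mean(axis=0)) > 3 * span:
        return None
    return center


def fit_ellipse(cluster: np.ndarray) -> tuple:
    """Center of the ellipse best fitting in-plane points.

    Returns ``(center_2d, used_fallback)``; with fewer than 5 points (an
    ellipse has 5 degrees of freedom) or a failed fit, falls back to the
    cluster centroid and flags it.
    """
    xy = np.atleast_2d(np.asarray(cluster, dtype=float))[:, :2]
    if len(xy) < 5:
        return xy.mean(axis=0), True
    center = _ellipse_center(xy)
    if center is None:
        return xy.mean(axis=0), True
    return center, False


def ransac_line(
    centers: np.ndarray,
    inlier_tol: float = 3.0,
    n_iter: int = 500,
    seed: int | np.random.Generator = 0,
) -> SkeletonLine:
    """Robust 3D line through the slice centers.

    Standard two-point-sample RANSAC maximizing the inlier count within
    ``inlier_tol``, followed by a total-least-squares refit (principal
    direction of the inlier scatter). Deterministic given the seed. The
    direction is oriented toward +z (toward the hand in the canonical frame),
    falling back to the largest-magnitude component being positive.
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    k = len(centers)
    if k < 2:
        raise ValueError("need at least 2 centers to fit a line")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def line_through(p, q):
        d = q - p
        n = np.linalg.norm(d)
        return None if n < 1e-12 else SkeletonLine(p, d / n)

    best_line, best_count, best_rms = None, -1, np.inf
    for _ in range(n_iter if k > 2 else 1):
        i, j = rng.choice(k, 2, replace=False)
        line = line_through(centers[i], centers[j])
        if line is None:
            continue
        d = line.distance(centers)
        inliers = d < inlier_tol
        count = int(inliers.sum())
        rms = float(np.sqrt(np.mean(d[inliers] ** 2))) if count else np.inf
        if count > best_count or (count == best_count and rms < best_rms):
            best_line, best_count, best_rms = line, count, rms
            best_inliers = inliers
    if best_line is None:
        raise DegenerateGeometryError("all slice centers coincide")
    pts = centers[best_inliers]
    if len(pts) >= 2 and np.linalg.norm(pts - pts.mean(axis=0), axis=1).max() > 1e-12:
        mean = pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts - mean, full_matrices=False)
        best_line = SkeletonLine(mean, vt[0])
    d = best_line.direction
    if abs(d[2]) > 1e-12:
        sign = np.sign(d[2])
    else:
        sign = np.sign(d[np.argmax(np.abs(d))])
    return SkeletonLine(best_line.point, sign * d)


def forearm_keypoints(line: SkeletonLine, barycenter, heights) -> ForearmKeyPoints:
    """FKPs: points of the line at signed distances ``heights`` from the
    projection of the barycenter onto the line."""
    heights = np.asarray(heights, dtype=float)
    if heights.size == 0:
        raise ValueError("heights must be nonempty")
    b = np.asarray(barycenter, dtype=float).reshape(3)
    foot = line.point + ((b - line.point) @ line.direction) * line.direction
    return ForearmKeyPoints(heights, foot + heights[:, None] * line.direction)


def detect_forearm_keypoints(
    cloud: PointCloud, hand_barycenter, cfg: ForearmConfig | None = None
):
    """Full forearm detection on a pose's merged cloud.

    Returns ``(ForearmKeyPoints, SkeletonLine, SliceSet)`` expressed in the
    cloud's own (pose) frame.
    """
    cfg = cfg or ForearmConfig()
    if len(cloud) < cfg.min_cloud_points:
        raise DegenerateGeometryError("cloud too small for forearm detection")
    canonical, transform = canonicalize(cloud, hand_barycenter)
    slices = slice_cloud(
        canonical, cfg.z_start, cfg.pitch, cfg.band, cfg.z_stop, cfg.min_slice_points
    )
    centers = []
    prev = None
    for zk, group in zip(slices.heights, slices.groups):
        if len(group) < cfg.min_slice_points:
            continue
        cluster = cluster_slice(group, cfg.cluster_eps, cfg.cluster_min_size, prev)
        if cluster is None:
            continue
        c2d, _ = fit_ellipse(cluster)
        center = np.array([c2d[0], c2d[1], zk])
        centers.append(center)
        prev = center
    if len(centers) < 2:
        raise DegenerateGeometryError("forearm not found: fewer than 2 slice centers")
    slices.centers = np.asarray(centers)
    line_canon = ransac_line(
        slices.centers, cfg.ransac_tol, cfg.ransac_iter, cfg.ransac_seed
    )
    fkp_canon = forearm_keypoints(line_canon, np.zeros(3), cfg.fkp_heights)
    back = transform.invert()
    fkps = ForearmKeyPoints(fkp_canon.heights, back.transform_points(fkp_canon.points))
    line = SkeletonLine(
        back.transform_points(line_canon.point[None])[0],
        back.transform_directions(line_canon.direction[None])[0],
    )
    return fkps, line, slices
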