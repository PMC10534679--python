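"""Synthetic multi-pose, multi-sensor scans of a parametric arm.

The simulator stands in for a handheld rig of three depth cameras mounted at
90 degrees on a circular frame and moved around the limb. The arm is a union
of analytic primitives — a conical-frustum forearm, an ellipsoid palm, and
five sphere-capped cylinder (capsule) chains for the fingers — with the 21
hand landmarks anchored on the primitive surfaces in the standard slot order.

Each scanner pose yields a :class:`Triplet`: three partially overlapping
point clouds expressed in that pose's own frame, per-sensor 21-slot landmark
detections with dropouts and confidence scores, and (simulator-only) the
ground-truth transform back to the world frame plus the indices of injected
outliers. Everything is a pure function of the model and the seeded config.

Sensor realism knobs: per-point visibility combines back-face culling with a
maximum incidence angle (stereo depth quality collapses at grazing
incidence), isotropic Gaussian depth noise, and two outlier populations —
gross random displacements and systematic "peripheral" outliers displaced
along the viewing ray at silhouette boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import PointCloud, RigidTransform, concatenate
from .keypoints import N_SLOTS, HandKeyPointSet

__all__ = [
    "ArmModel",
    "ScanSimConfig",
    "Triplet",
    "build_arm_model",
    "simulate_scan",
    "make_dataset",
    "visible_mask",
]


# ---------------------------------------------------------------------------
# analytic primitives
# ---------------------------------------------------------------------------


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _dist_to_segment(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Euclidean distance from each point to the segment ab (vectorized)."""
    ab = b - a
    t = np.clip((points - a) @ ab / (ab @ ab), 0.0, 1.0)
    closest = a + t[:, None] * ab
    return np.linalg.norm(points - closest, axis=1)


@dataclass
class _Frustum:
    """Conical frustum along z: radius r_top at z=0, r_bottom at z=-length."""

    length: float
    r_top: float
    r_bottom: float

    def radius_at(self, z):
        return self.r_top - (self.r_bottom - self.r_top) * z / self.length

    def area(self) -> float:
        slant = np.hypot(self.length, self.r_bottom - self.r_top)
        return np.pi * (self.r_top + self.r_bottom) * slant

    def sample(self, n: int, rng: np.random.Generator):
        # z by inverse CDF of the linear radius density (area element ~ r(z))
        u = rng.random(n)
        rt, rb = self.r_top, self.r_bottom
        s = (np.sqrt(rt**2 + u * (rb**2 - rt**2)) - rt) / (rb - rt)  # s in [0,1]
        z = -self.length * s
        theta = rng.uniform(0, 2 * np.pi, n)
        r = self.radius_at(z)
        pts = np.c_[r * np.cos(theta), r * np.sin(theta), z]
        slope = (self.r_bottom - self.r_top) / self.length
        normals = np.c_[np.cos(theta), np.sin(theta), np.full(n, slope)]
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        return pts, normals

    def surface_distance(self, points: np.ndarray) -> np.ndarray:
        # 2D distance to the slant segment in the (radius, z) half-plane
        rho = np.linalg.norm(points[:, :2], axis=1)
        pz = np.c_[rho, points[:, 2], np.zeros(len(points))]
        a = np.array([self.r_top, 0.0, 0.0])
        b = np.array([self.r_bottom, -self.length, 0.0])
        return _dist_to_segment(pz, a, b)

    def contains(self, points: np.ndarray, margin: float) -> np.ndarray:
        rho = np.linalg.norm(points[:, :2], axis=1)
        z = points[:, 2]
        inside_z = (z > -self.length) & (z < 0.0)
        return inside_z & (rho < self.radius_at(np.clip(z, -self.length, 0.0)) - margin)


@dataclass
class _Ellipsoid:
    center: np.ndarray
    semi_axes: np.ndarray

    def area(self) -> float:
        a, b, c = self.semi_axes
        p = 1.6075
        return 4 * np.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3) ** (1 / p)

    def sample(self, n: int, rng: np.random.Generator):
        a, b, c = self.semi_axes
        gmax = max(a * b, b * c, a * c)
        pts = np.empty((0, 3))
        while len(pts) < n:
            m = 2 * (n - len(pts)) + 16
            u = rng.normal(size=(m, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            g = np.linalg.norm(u * [b * c, a * c, a * b], axis=1)
            keep = rng.random(m) < g / gmax
            pts = np.vstack([pts, u[keep] * self.semi_axes])
        pts = pts[:n]
        normals = pts / self.semi_axes**2
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        return pts + self.center, normals

    def _k(self, points: np.ndarray) -> np.ndarray:
        return np.linalg.norm((points - self.center) / self.semi_axes, axis=1)

    def surface_distance(self, points: np.ndarray) -> np.ndarray:
        # radial approximation; exact on the surface itself
        k = np.maximum(self._k(points), 1e-12)
        return np.linalg.norm(points - self.center, axis=1) * np.abs(1 - 1 / k)

    def contains(self, points: np.ndarray, margin: float) -> np.ndarray:
        return self._k(points) < 1 - margin / float(self.semi_axes.min())


@dataclass
class _Capsule:
    """Sphere-swept segment: cylinder with hemispherical end caps."""

    a: np.ndarray
    b: np.ndarray
    radius: float
    tip: bool = False  # sample the distal hemisphere cap (fingertips)

    def area(self) -> float:
        length = np.linalg.norm(self.b - self.a)
        lateral = 2 * np.pi * self.radius * length
        return lateral + (2 * np.pi * self.radius**2 if self.tip else 0.0)

    def sample(self, n: int, rng: np.random.Generator):
        d = _unit(self.b - self.a)
        length = np.linalg.norm(self.b - self.a)
        cap_area = 2 * np.pi * self.radius**2 if self.tip else 0.0
        n_cap = rng.binomial(n, cap_area / (cap_area + 2 * np.pi * self.radius * length))
        # cylinder part
        e1 = _unit(np.cross(d, [0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.cross(d, [1.0, 0.0, 0.0]))
        e2 = np.cross(d, e1)
        m = n - n_cap
        t = rng.uniform(0, length, m)
        theta = rng.uniform(0, 2 * np.pi, m)
        radial = np.outer(np.cos(theta), e1) + np.outer(np.sin(theta), e2)
        pts = self.a + np.outer(t, d) + self.radius * radial
        normals = radial
        if n_cap:
            v = rng.normal(size=(n_cap, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            flip = v @ d < 0
            v[flip] -= 2 * np.outer((v @ d)[flip], d)
            pts = np.vstack([pts, self.b + self.radius * v])
            normals = np.vstack([normals, v])
        return pts, normals

    def surface_distance(self, points: np.ndarray) -> np.ndarray:
        return np.abs(_dist_to_segment(points, self.a, self.b) - self.radius)

    def contains(self, points: np.ndarray, margin: float) -> np.ndarray:
        return _dist_to_segment(points, self.a, self.b) < self.radius - margin


# ---------------------------------------------------------------------------
# arm model
# ---------------------------------------------------------------------------

_FINGER_NAMES = ("thumb", "index", "middle", "ring", "pinky")


@dataclass
class ArmModel:
    """Parametric arm: frustum forearm + ellipsoid palm + five capsule-chain fingers.

    The forearm axis is the z-axis; the wrist plane is z = 0 with the forearm
    extending to z = -forearm_length and the hand above. ``hand_keypoints``
    holds the 21 anatomical anchors on the model surface in the fixed slot
    order (0 = wrist, 4 per finger starting with the thumb).
    """

    forearm_length: float = 250.0
    forearm_proximal_radius: float = 45.0  # elbow end
    forearm_distal_radius: float = 30.0  # wrist end
    palm_center: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 50.0]))
    palm_semi_axes: np.ndarray = field(default_factory=lambda: np.array([40.0, 22.0, 55.0]))
    finger_radii: dict = field(
        default_factory=lambda: {"thumb": 9.0, "index": 8.0, "middle": 8.5, "ring": 8.0, "pinky": 7.0}
    )
    finger_segments: dict = field(
        default_factory=lambda: {
            "thumb": (42.0, 32.0, 25.0),
            "index": (40.0, 25.0, 18.0),
            "middle": (45.0, 28.0, 20.0),
            "ring": (42.0, 26.0, 19.0),
            "pinky": (32.0, 20.0, 15.0),
        }
    )

    def __post_init__(self) -> None:
        if min(
            self.forearm_length,
            self.forearm_proximal_radius,
            self.forearm_distal_radius,
            *self.finger_radii.values(),
        ) <= 0 or (np.asarray(self.palm_semi_axes) <= 0).any():
            raise ValueError("model dimensions must be positive")
        self.palm_center = np.asarray(self.palm_center, dtype=float)
        self.palm_semi_axes = np.asarray(self.palm_semi_axes, dtype=float)
        self._build()

    def _build(self) -> None:
        self._frustum = _Frustum(
            self.forearm_length, self.forearm_distal_radius, self.forearm_proximal_radius
        )
        self._palm = _Ellipsoid(self.palm_center, self.palm_semi_axes)
        cx, _, cz = self.palm_center
        ax, _, az = self.palm_semi_axes
        bases, dirs = {}, {}
        for name, x in zip(_FINGER_NAMES[1:], (-30.0, -10.0, 10.0, 30.0)):
            bases[name] = np.array([cx + x, 0.0, cz + az * np.sqrt(max(1 - (x / ax) ** 2, 0.0))])
            dirs[name] = _unit(np.array([0.3 * x / 30.0, 0.0, 1.0]))
        bases["thumb"] = np.array([cx - ax, 0.0, cz])
        dirs["thumb"] = _unit(np.array([-0.8, 0.0, 0.6]))

        self._fingers: dict[str, list[_Capsule]] = {}
        keypoints = [np.array([0.0, self.forearm_distal_radius, 0.0])]  # slot 0: wrist
        for name in _FINGER_NAMES:
            r = self.finger_radii[name]
            d = dirs[name]
            joints = [bases[name]]
            for seg_len in self.finger_segments[name]:
                joints.append(joints[-1] + seg_len * d)
            chain = [
                _Capsule(joints[i], joints[i + 1], r, tip=(i == 2)) for i in range(3)
            ]
            self._fingers[name] = chain
            dorsal = _unit(np.array([0.0, 1.0, 0.0]) - d[1] * d)
            keypoints.extend(joints[i] + r * dorsal for i in range(3))
            keypoints.append(joints[3] + r * d)  # fingertip on the cap
        self.hand_keypoints = np.asarray(keypoints)
        assert self.hand_keypoints.shape == (N_SLOTS, 3)
        self._primitives = [self._frustum, self._palm] + [
            c for chain in self._fingers.values() for c in chain
        ]

    # -- geometry queries ---------------------------------------------------

    def surface_distance(self, points) -> np.ndarray:
        """Unsigned distance from each point to the nearest primitive surface."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return np.min([p.surface_distance(points) for p in self._primitives], axis=0)

    def z_extent(self):
        top = self.hand_keypoints[:, 2].max()
        return -self.forearm_length, float(top)

    def sample_surface(self, n: int, rng: np.random.Generator):
        """Area-weighted surface sample; points buried inside another primitive
        are rejected so the sample lies on the boundary of the union."""
        areas = np.array([p.area() for p in self._primitives])
        counts = rng.multinomial(n, areas / areas.sum())
        pts, nrm = [], []
        for i, (prim, c) in enumerate(zip(self._primitives, counts)):
            if c == 0:
                continue
            p, nv = prim.sample(c, rng)
            buried = np.zeros(len(p), dtype=bool)
            for j, other in enumerate(self._primitives):
                if j != i:
                    buried |= other.contains(p, margin=0.3)
            pts.append(p[~buried])
            nrm.append(nv[~buried])
        return np.vstack(pts), np.vstack(nrm)


def build_arm_model(**params) -> ArmModel:
    """Construct an :class:`ArmModel`; keyword arguments override the defaults."""
    return ArmModel(**params)


# ---------------------------------------------------------------------------
# scan simulation
# ---------------------------------------------------------------------------


@dataclass
class ScanSimConfig:
    """Study conditions for the simulated acquisition.

    The rig holds three sensors 90 degrees apart on a ring of radius
    ``ring_radius`` (the sensors' sweet spot is 250-450 mm from the surface);
    ``n_poses`` ring placements are distributed around the limb axis. Depth
    noise is isotropic Gaussian; ``outlier_fraction`` of each cloud is split
    between gross random outliers and systematic peripheral ones. Landmark
    detections drop slots independently with ``keypoint_dropout_prob`` and
    carry a per-image confidence drawn from ``score_range``.
    """

    n_poses: int = 6
    ring_radius: float = 350.0
    sensor_angles: tuple = (-90.0, 0.0, 90.0)
    working_distance: tuple = (250.0, 450.0)
    max_incidence_deg: float = 32.0
    n_points_per_sensor: int = 8000
    noise_sigma: float = 0.5
    outlier_fraction: float = 0.02
    outlier_magnitude: float = 30.0
    keypoint_dropout_prob: float = 0.1
    score_range: tuple = (0.7, 0.99)
    pose_tilt_deg: float = 3.0
    pose_shift_mm: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.outlier_fraction <= 1 and 0 <= self.keypoint_dropout_prob <= 1):
            raise ValueError("fractions and probabilities must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        lo, hi = self.score_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("score_range must be an interval inside [0, 1]")
        diffs = np.diff(self.sensor_angles)
        if not np.allclose(diffs, 90.0):
            raise ValueError("sensor angular spacing must be 90 degrees")
        if self.n_poses < 1:
            raise ValueError("n_poses must be >= 1")


@dataclass
class Triplet:
    """One scanner pose: three co-registered clouds + per-sensor detections.

    ``truth_transform`` (pose frame -> world) and ``outlier_indices`` are
    simulator ground truth, available only to tests and evaluation — the
    registration pipeline never reads them.
    """

    clouds: list
    detections: list
    pose_id: int
    truth_transform: RigidTransform | None = None
    outlier_indices: list | None = None

    def merged(self) -> PointCloud:
        """The three sensor clouds stacked in the pose's common frame."""
        return concatenate(self.clouds)


def visible_mask(
    points: np.ndarray,
    normals: np.ndarray,
    sensor_position: np.ndarray,
    max_incidence_deg: float = 90.0,
) -> np.ndarray:
    """Which surface points a sensor at ``sensor_position`` can see.

    A point is visible when its outward normal faces the sensor within
    ``max_incidence_deg`` (90 degrees = pure back-face culling).
    """
    view = np.asarray(sensor_position, dtype=float) - points
    view /= np.linalg.norm(view, axis=1, keepdims=True)
    cosines = np.einsum("ij,ij->i", np.asarray(normals), view)
    return cosines > np.cos(np.radians(max_incidence_deg))


def _rotz(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _pose_truth(pose_index: int, cfg: ScanSimConfig, rng: np.random.Generator) -> RigidTransform:
    angle = 2 * np.pi * pose_index / cfg.n_poses
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    tilt = np.radians(cfg.pose_tilt_deg) * rng.random()
    from scipy.spatial.transform import Rotation

    r_tilt = Rotation.from_rotvec(tilt * axis).as_matrix()
    shift = rng.uniform(-cfg.pose_shift_mm, cfg.pose_shift_mm, 3)
    return RigidTransform(_rotz(angle) @ r_tilt, shift)


def simulate_scan(model: ArmModel, pose_index: int, cfg: ScanSimConfig) -> Triplet:
    """Simulate one scanner pose; pure function of (model, cfg, pose_index)."""
    if pose_index >= cfg.n_poses:
        raise ValueError("pose_index must be < n_poses")
    rng = np.random.default_rng(cfg.seed + pose_index)
    truth = _pose_truth(pose_index, cfg, rng)
    inv = truth.invert()

    pts_w, nrm_w = model.sample_surface(cfg.n_points_per_sensor * 5, rng)
    zmin, zmax = model.z_extent()
    z_mid = 0.5 * (zmin + zmax)
    pose_azimuth = 2 * np.pi * pose_index / cfg.n_poses

    clouds, detections, outlier_lists = [], [], []
    for sensor_id, rel_angle in enumerate(cfg.sensor_angles):
        phi = pose_azimuth + np.radians(rel_angle)
        sensor_pos = np.array(
            [cfg.ring_radius * np.cos(phi), cfg.ring_radius * np.sin(phi), z_mid]
        )
        vis = visible_mask(pts_w, nrm_w, sensor_pos, cfg.max_incidence_deg)
        dist = np.linalg.norm(pts_w - sensor_pos, axis=1)
        vis &= (dist >= cfg.working_distance[0]) & (dist <= cfg.working_distance[1])
        idx = np.flatnonzero(vis)
        if len(idx) > cfg.n_points_per_sensor:
            idx = np.sort(rng.choice(idx, cfg.n_points_per_sensor, replace=False))
        pts = pts_w[idx].copy()
        nrm = nrm_w[idx]
        view = sensor_pos - pts
        view /= np.linalg.norm(view, axis=1, keepdims=True)

        if cfg.noise_sigma > 0:
            pts = pts + rng.normal(0.0, cfg.noise_sigma, pts.shape)

        n_out = int(round(cfg.outlier_fraction * len(pts)))
        out_idx = np.empty(0, dtype=int)
        if n_out:
            n_rand = n_out // 2
            n_peri = n_out - n_rand
            rand_idx = rng.choice(len(pts), n_rand, replace=False)
            dirs = rng.normal(size=(n_rand, 3))
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            pts[rand_idx] += dirs * (cfg.outlier_magnitude * (0.5 + 0.5 * rng.random(n_rand)))[:, None]
            # peripheral outliers: lowest-incidence (silhouette) points pushed along the ray
            cosines = np.einsum("ij,ij->i", nrm, view)
            order = np.argsort(cosines)
            peri_idx = np.array([i for i in order if i not in set(rand_idx)][:n_peri], dtype=int)
            shift = cfg.outlier_magnitude * rng.uniform(0.3, 1.0, len(peri_idx))
            pts[peri_idx] -= view[peri_idx] * shift[:, None]
            out_idx = np.sort(np.concatenate([rand_idx, peri_idx]))

        cloud = PointCloud(
            inv.transform_points(pts),
            inv.transform_directions(nrm),
            labels=np.full(len(pts), sensor_id),
        )
        clouds.append(cloud)
        outlier_lists.append(out_idx)

        kp = inv.transform_points(model.hand_keypoints)
        dropped = rng.random(N_SLOTS) < cfg.keypoint_dropout_prob
        coords = kp.copy()
        coords[dropped] = np.nan
        score = float(rng.uniform(*cfg.score_range))
        detections.append(HandKeyPointSet(coords, score=score, sensor_id=sensor_id))

    return Triplet(clouds, detections, pose_index, truth, outlier_lists)


def make_dataset(model: ArmModel, cfg: ScanSimConfig) -> list:
    """All poses around the limb (equal angular steps, partial overlap)."""
    return [simulate_scan(model, i, cfg) for i in range(cfg.n_poses)]
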