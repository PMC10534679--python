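"""Fine registration by constrained minimization of 1/(f1 * f2).

For a fixed cloud (M points) and a moving cloud (N points), the pair set D
collects every index pair (i, j) whose Euclidean distance is below the
threshold ``toll``. Two terms measure alignment:

    f1 = |D| / min(M, N)          -- matched-pair fraction within toll
    f2 = sum_(i,j) in D  n_i . n_j / |D|   -- mean normal agreement over D

and the pose minimizing 1/(f1 * f2) over six bounded degrees of freedom
(three Euler angles about the moving centroid plus a translation) is found
with sequential least-squares programming (SLSQP) using finite-difference
gradients. When |D| = 0 or f2 <= 0 the objective takes a large penalty
constant that steers the optimizer back toward overlap.

Because |D| follows the literal full M x N definition, a point may belong to
several pairs, and f1 can exceed 1 on dense clouds; the 0.75 mm voxel grid
applied before optimization bounds this multiplicity at toll = 1.5 mm.

The global stage (multi-cloud loop) repeatedly draws a random fixed cloud,
relabels the rest in acquisition (clockwise) order from it, and registers
each in turn against the accumulated, re-voxelized union of already-aligned
clouds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .geometry import (
    PointCloud,
    RigidTransform,
    apply_transform,
    concatenate,
    estimate_normals,
    sor_filter,
    voxel_downsample,
)

__all__ = [
    "FineRegConfig",
    "ObjectiveValue",
    "pair_set",
    "objective",
    "preprocess",
    "fine_register_pair",
    "global_fine_register",
]

PENALTY = 1.0e6


@dataclass
class FineRegConfig:
    """Fine-registration parameters (lengths in mm, angles in radians).

    Defaults: pair threshold toll = 1.5 mm, voxel grid 0.75 mm, SLSQP stop
    tolerance 1e-4 on the objective change, 9 outer epochs for the global
    loop, and box bounds of +-10 degrees / +-10 mm around the incoming pose.
    """

    toll: float = 1.5
    voxel: float = 0.75
    bounds_rot: float = np.radians(10.0)
    bounds_trans: float = 10.0
    stop_tol: float = 1.0e-4
    max_eval: int = 700
    n_iter_ex: int = 9
    seed: int = 0
    sor_k: int = 20
    sor_std_ratio: float = 2.0
    normal_k: int = 30
    fd_rot_step: float = 1.0e-3  # finite-difference step, radians
    fd_trans_step: float = 0.1  # finite-difference step, mm
    # coarse-to-fine multipliers of the finite-difference steps; the count-based
    # f1 term is piecewise-flat, so early rounds need steps that straddle
    # pair-set changes and later rounds resolve the basin
    fd_schedule: tuple = (10.0, 3.0, 1.0)
    max_restarts: int = 3
    # Quasi-cylindrical surfaces leave a weakly observed "sliding" gauge —
    # rotation about and translation along the limb axis — whose capture basin
    # is much narrower than the box bounds. When the first descent moves the
    # pose materially (i.e. the incoming pose was far from converged), a grid
    # scan over the sliding plane around the descent's endpoint re-seeds a
    # final descent. Near-converged starts skip the scan.
    slide_scan: bool = True
    slide_rounds: int = 3
    # gated lateral multi-start: tilts (degrees) about the two axes
    # perpendicular to the limb axis, to escape "see-saw" local minima where
    # only the mid-section of a long cloud stays paired
    tilt_starts: tuple = (-6.0, -3.0, 3.0, 6.0)
    slide_rot_steps: int = 21
    slide_trans_steps: int = 13
    slide_engage_rot: float = np.radians(0.5)  # displacement that triggers the scan
    slide_engage_trans: float = 0.75

    def __post_init__(self) -> None:
        if self.toll <= 0 or self.voxel <= 0 or self.stop_tol <= 0 or self.n_iter_ex < 1:
            raise ValueError("toll, voxel, stop_tol must be positive; n_iter_ex >= 1")


@dataclass
class ObjectiveValue:
    """One evaluation of the fine-registration objective."""

    f1: float
    f2: float
    value: float
    n_pairs: int

    @property
    def is_penalty(self) -> bool:
        return self.value >= PENALTY


def pair_set(fixed: PointCloud, moving: PointCloud, toll: float):
    """All index pairs (i, j, d_ij) with d_ij < toll, via a spatial radius search.

    Logically identical to the full M x N distance matrix with NULL entries
    dropped.
    """
    if len(fixed) == 0 or len(moving) == 0:
        raise ValueError("clouds must be nonempty")
    pairs = cKDTree(fixed.points).sparse_distance_matrix(
        cKDTree(moving.points), max_distance=toll, output_type="ndarray"
    )
    strict = pairs["v"] < toll
    return pairs["i"][strict], pairs["j"][strict], pairs["v"][strict]


def _pairs_from_tree(tree_f, n_fixed, moving_pts, toll, k0: int = 16):
    """Exact (i, j) pairs with d < toll via capped kNN with doubling on overflow."""
    k = min(k0, n_fixed)
    while True:
        dists, idx = tree_f.query(moving_pts, k=k, distance_upper_bound=toll)
        if k == 1:
            dists, idx = dists[:, None], idx[:, None]
        hit = dists < toll
        if k >= n_fixed or not hit[:, -1].any():
            break
        k = min(k * 2, n_fixed)  # some row may have been truncated
    return idx[hit], np.repeat(np.arange(len(moving_pts)), hit.sum(axis=1))


def _objective_arrays(
    fixed_pts, fixed_normals, moving_pts, moving_normals, toll, fixed_tree=None
) -> ObjectiveValue:
    tree_f = fixed_tree if fixed_tree is not None else cKDTree(fixed_pts)
    i, j = _pairs_from_tree(tree_f, len(fixed_pts), moving_pts, toll)
    nd = len(i)
    denom = min(len(fixed_pts), len(moving_pts))
    f1 = nd / denom
    if nd == 0:
        return ObjectiveValue(0.0, 0.0, PENALTY, 0)
    f2 = float(np.einsum("ij,ij->", fixed_normals[i], moving_normals[j])) / nd
    if f2 <= 0:
        return ObjectiveValue(f1, f2, PENALTY, nd)
    return ObjectiveValue(f1, f2, 1.0 / (f1 * f2), nd)


def objective(fixed: PointCloud, moving: PointCloud, toll: float) -> ObjectiveValue:
    """Evaluate f1, f2 and 1/(f1*f2) for the current relative pose."""
    if fixed.normals is None or moving.normals is None:
        raise ValueError("normals required")
    return _objective_arrays(
        fixed.points, fixed.normals, moving.points, moving.normals, toll
    )


def preprocess(cloud: PointCloud, cfg: FineRegConfig | None = None) -> PointCloud:
    """SOR outlier removal, voxel-grid downsampling, then normal estimation."""
    cfg = cfg or FineRegConfig()
    kept, _ = sor_filter(cloud, cfg.sor_k, cfg.sor_std_ratio)
    down = voxel_downsample(kept, cfg.voxel)
    return estimate_normals(down, cfg.normal_k)


def fine_register_pair(
    fixed: PointCloud, moving: PointCloud, cfg: FineRegConfig | None = None
):
    """Bounded 6-DOF SLSQP refinement of ``moving`` onto ``fixed``.

    Both clouds must carry normals (see :func:`preprocess`) and be coarsely
    aligned already. Rotation is parameterized as xyz Euler angles
    about the moving cloud's centroid; variables are scaled so a unit
    finite-difference step equals ``fd_rot_step`` / ``fd_trans_step``, which
    must straddle pair-set changes because the count-based f1 term makes the
    objective piecewise-flat.

    Returns
    -------
    (RigidTransform, list[float], ObjectiveValue, str | None)
        Best transform found, the trace of the best objective value at each
        accepted iterate (monotone non-increasing), the final objective, and
        a flag ("no_overlap") when the objective is penalty-valued everywhere
        in the probe neighborhood of the start.
    """
    cfg = cfg or FineRegConfig()
    if fixed.normals is None or moving.normals is None:
        raise ValueError("normals required")
    center = moving.points.mean(axis=0)
    tree_f = cKDTree(fixed.points)
    mp, mn = moving.points, moving.normals

    def transform_of(x: np.ndarray) -> RigidTransform:
        angles = np.asarray(x[:3]) * cfg.fd_rot_step
        t = np.asarray(x[3:]) * cfg.fd_trans_step
        rot = Rotation.from_euler("xyz", angles).as_matrix()
        return RigidTransform(rot, center - rot @ center + t)

    best = {"value": np.inf, "x": np.zeros(6), "obj": None}

    def fun(x: np.ndarray) -> float:
        transform = transform_of(x)
        pts = transform.transform_points(mp)
        nrm = transform.transform_directions(mn)
        obj = _objective_arrays(fixed.points, fixed.normals, pts, nrm, cfg.toll, tree_f)
        if obj.value < best["value"]:
            best.update(value=obj.value, x=np.array(x), obj=obj)
        return obj.value

    x0 = np.zeros(6)
    f0 = fun(x0)
    if f0 >= PENALTY:
        probes = np.vstack([np.eye(6), -np.eye(6)]) * 5.0
        if all(fun(p) >= PENALTY for p in probes):
            return (
                RigidTransform.identity(),
                [f0],
                ObjectiveValue(0.0, 0.0, PENALTY, 0),
                "no_overlap",
            )

    br = cfg.bounds_rot / cfg.fd_rot_step
    bt = cfg.bounds_trans / cfg.fd_trans_step
    bounds = [(-br, br)] * 3 + [(-bt, bt)] * 3
    trace = [f0]

    def callback(xk):
        trace.append(min(trace[-1], fun(xk)))

    maxiter = max(cfg.max_eval // 7, 5)

    def slsqp(x_start, eps):
        return minimize(
            fun,
            x_start,
            method="SLSQP",
            bounds=bounds,
            callback=callback,
            options={"ftol": cfg.stop_tol, "maxiter": maxiter, "eps": eps},
        )

    def descend(x_start, f_start=np.inf):
        x_cur, f_cur = np.asarray(x_start, dtype=float), f_start
        for eps in cfg.fd_schedule:
            for _ in range(cfg.max_restarts):
                res = slsqp(x_cur, eps)
                improved = f_cur - res.fun
                if res.fun < f_cur:
                    x_cur, f_cur = res.x, res.fun
                if improved < cfg.stop_tol:
                    break
        return x_cur

    # fast path: fine-step descents settle a near-converged pose without the
    # coarse-step schedule or the capture machinery below
    f_prev = f0
    for _ in range(cfg.max_restarts):
        slsqp(best["x"], cfg.fd_schedule[-1])
        if f_prev - best["value"] < cfg.stop_tol:
            break
        f_prev = best["value"]
    moved_rot = np.abs(best["x"][:3] * cfg.fd_rot_step).max()
    moved_trans = np.abs(best["x"][3:] * cfg.fd_trans_step).max()
    converged = (
        moved_rot <= cfg.slide_engage_rot and moved_trans <= cfg.slide_engage_trans
    )
    if not converged:
        descend(best["x"], best["value"])
        moved_rot = np.abs(best["x"][:3] * cfg.fd_rot_step).max()
        moved_trans = np.abs(best["x"][3:] * cfg.fd_trans_step).max()
    if not converged and cfg.slide_scan and (
        moved_rot > cfg.slide_engage_rot or moved_trans > cfg.slide_engage_trans
    ):
        from .geometry import inertia_frame

        frame = inertia_frame(moving)
        for ax in (frame.axes[1], frame.axes[2]):
            for ang_deg in cfg.tilt_starts:
                rotvec = np.radians(ang_deg) * ax
                rot = Rotation.from_rotvec(rotvec)
                x_tilt = np.concatenate(
                    [rot.as_euler("xyz") / cfg.fd_rot_step, best["x"][3:]]
                )
                if np.all(np.abs(x_tilt[:3]) <= br):
                    descend(x_tilt)
        for _ in range(cfg.slide_rounds):
            before = best["value"]
            _slide_scan(fun, transform_of, best["x"], moving, cfg, bounds)
            descend(best["x"])
            if before - best["value"] < cfg.stop_tol:
                break
    trace.append(min(trace[-1], best["value"]))
    return transform_of(best["x"]), trace, best["obj"], None


def _slide_scan(fun, transform_of, x_base, moving, cfg, bounds):
    """Evaluate a grid of sliding-mode candidates around the current pose.

    The sliding plane is spanned by rotation about, and translation along,
    the moving cloud's lowest-inertia (limb) axis at its current pose.
    Candidates falling outside the box bounds are skipped; every evaluation
    goes through ``fun`` so the best-pose tracker sees them.
    """
    from .geometry import inertia_frame

    base = transform_of(x_base)
    axis = inertia_frame(moving).axes[0]
    axis = base.transform_directions(axis[None])[0]
    center = base.transform_points(moving.points.mean(axis=0)[None])[0]
    mcen = moving.points.mean(axis=0)
    angles = np.linspace(-cfg.bounds_rot, cfg.bounds_rot, cfg.slide_rot_steps)
    shifts = np.linspace(-cfg.bounds_trans * 0.9, cfg.bounds_trans * 0.9, cfg.slide_trans_steps)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    for theta in angles:
        rot = Rotation.from_rotvec(theta * axis).as_matrix()
        for s in shifts:
            if theta == 0.0 and s == 0.0:
                continue
            extra = RigidTransform(rot, center - rot @ center + s * axis)
            cand = extra.compose(base)
            ang = Rotation.from_matrix(cand.rotation).as_euler("xyz")
            tv = cand.translation - (mcen - cand.rotation @ mcen)
            x = np.concatenate([ang / cfg.fd_rot_step, tv / cfg.fd_trans_step])
            if np.all(x >= lo) and np.all(x <= hi):
                fun(x)


def global_fine_register(clouds, cfg: FineRegConfig | None = None, preprocessed=None):
    """Multi-cloud fine registration loop.

    ``clouds`` are the coarse-aligned clouds in acquisition (clockwise)
    order. For each of ``n_iter_ex`` epochs a fixed cloud index is drawn at
    random (seeded); the remaining clouds, relabeled clockwise from it, are
    registered one by one against the accumulated fixed cloud, which absorbs
    (union + re-voxelization) each aligned cloud as it goes.

    Returns
    -------
    (list[RigidTransform], list)
        Cumulative transform per input cloud (original order) and a list of
        (epoch, cloud index, flag) for pairs that had to keep their previous
        pose.
    """
    cfg = cfg or FineRegConfig()
    clouds = list(clouds)
    n = len(clouds)
    cumulative = [RigidTransform.identity() for _ in range(n)]
    if n == 1:
        return cumulative, []
    pre = preprocessed if preprocessed is not None else [preprocess(c, cfg) for c in clouds]
    pre = list(pre)
    rng = np.random.default_rng(cfg.seed)
    flags = []
    for epoch in range(cfg.n_iter_ex):
        fixed_idx = int(rng.integers(0, n))
        order = [(fixed_idx + m) % n for m in range(n)]
        accumulated = pre[order[0]]
        for k in order[1:]:
            transform, _, _, flag = fine_register_pair(accumulated, pre[k], cfg)
            if flag is not None:
                flags.append((epoch, k, flag))
            else:
                pre[k] = apply_transform(transform, pre[k])
                cumulative[k] = transform.compose(cumulative[k])
            accumulated = voxel_downsample(concatenate([accumulated, pre[k]]), cfg.voxel)
    return cumulative, flags
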