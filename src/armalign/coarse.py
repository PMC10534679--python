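"""Key-point-based coarse registration of scanner poses.

The pose with the most recognized hand landmarks becomes the fixed reference;
every other pose is aligned to it (star topology) by solving the weighted
absolute-orientation problem over the matched hand landmarks (slot
intersection) and forearm key points (matched by height index) with Horn's
quaternion method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forearm import ForearmKeyPoints
from .geometry import RigidTransform, horn_weighted_orientation
from .keypoints import MIN_COMMON, HandKeyPointSet, intersect_keypoints

__all__ = [
    "RegistrationFailure",
    "Correspondences",
    "CoarseResult",
    "select_fixed_triplet",
    "build_correspondences",
    "coarse_register_all",
]


class RegistrationFailure(RuntimeError):
    """A pose cannot be registered automatically; an operator must intervene."""


@dataclass
class Correspondences:
    """Matched fixed/moving 3D pairs with weights and provenance."""

    fixed: np.ndarray
    moving: np.ndarray
    weights: np.ndarray
    hand_slots: np.ndarray
    n_fkp: int

    def __len__(self) -> int:
        return len(self.fixed)


@dataclass
class CoarseResult:
    fixed_index: int
    transforms: list  # RigidTransform per pose (identity for the fixed one)
    used: list  # per pose: dict with hand slot indices and FKP count, or None
    residual_rms: list  # mm per pose (0 for the fixed one, NaN for failures)
    failed: list = field(default_factory=list)  # (pose index, reason)

    @property
    def ok(self) -> bool:
        return not self.failed


def select_fixed_triplet(keypoint_sets) -> int:
    """Index of the pose with the most valid hand landmarks (ties: lowest index).

    ``keypoint_sets`` holds each pose's best-sensor 3D landmark set (or None
    when selection failed for that pose).
    """
    best_i, best_n = None, MIN_COMMON - 1
    for i, kp in enumerate(keypoint_sets):
        if kp is not None and kp.n_valid > best_n:
            best_i, best_n = i, kp.n_valid
    if best_i is None:
        raise RegistrationFailure(
            "coarse registration impossible: no pose has >= 3 valid hand key points"
        )
    return best_i


def build_correspondences(
    fixed_kp: HandKeyPointSet | None,
    fixed_fkp: ForearmKeyPoints | None,
    moving_kp: HandKeyPointSet | None,
    moving_fkp: ForearmKeyPoints | None,
    w_hand: float = 1.0,
    w_fkp: float = 1.0,
) -> Correspondences:
    """Hand pairs by slot intersection plus forearm pairs matched by height index."""
    fixed_pts, moving_pts, weights = [], [], []
    hand_slots = np.empty(0, dtype=int)
    if fixed_kp is not None and moving_kp is not None:
        corr = intersect_keypoints(fixed_kp, moving_kp)
        hand_slots = corr.indices
        if len(corr.indices):
            fixed_pts.append(corr.fixed)
            moving_pts.append(corr.moving)
            weights.append(np.full(len(corr.indices), w_hand))
    n_fkp = 0
    if fixed_fkp is not None and moving_fkp is not None:
        common = np.isin(fixed_fkp.heights, moving_fkp.heights)
        idx_m = np.searchsorted(-moving_fkp.heights, -fixed_fkp.heights[common])
        n_fkp = int(common.sum())
        if n_fkp:
            fixed_pts.append(fixed_fkp.points[common])
            moving_pts.append(moving_fkp.points[idx_m])
            weights.append(np.full(n_fkp, w_fkp))
    total = sum(len(p) for p in fixed_pts)
    if total < MIN_COMMON:
        raise RegistrationFailure(
            f"manual intervention required: only {total} correspondences"
        )
    return Correspondences(
        np.vstack(fixed_pts), np.vstack(moving_pts), np.concatenate(weights), hand_slots, n_fkp
    )


def coarse_register_all(
    keypoint_sets,
    forearm_sets=None,
    w_hand: float = 1.0,
    w_fkp: float = 1.0,
) -> CoarseResult:
    """Register every pose to the fixed reference via Horn's method.

    Poses whose correspondences fail are flagged (identity transform, NaN
    residual) rather than silently dropped.
    """
    keypoint_sets = list(keypoint_sets)
    n = len(keypoint_sets)
    forearm_sets = list(forearm_sets) if forearm_sets is not None else [None] * n
    fixed_index = select_fixed_triplet(keypoint_sets)
    fixed_kp = keypoint_sets[fixed_index]
    fixed_fkp = forearm_sets[fixed_index]

    transforms, used, residuals, failed = [], [], [], []
    for i in range(n):
        if i == fixed_index:
            transforms.append(RigidTransform.identity())
            used.append({"hand_slots": fixed_kp.valid_indices, "n_fkp": 0})
            residuals.append(0.0)
            continue
        try:
            corr = build_correspondences(
                fixed_kp, fixed_fkp, keypoint_sets[i], forearm_sets[i], w_hand, w_fkp
            )
            transform = horn_weighted_orientation(corr.moving, corr.fixed, corr.weights)
            res = transform.transform_points(corr.moving) - corr.fixed
            w = corr.weights / corr.weights.sum()
            rms = float(np.sqrt(np.sum(w * np.einsum("ij,ij->i", res, res))))
            transforms.append(transform)
            used.append({"hand_slots": corr.hand_slots, "n_fkp": corr.n_fkp})
            residuals.append(rms)
        except (RegistrationFailure, ValueError) as exc:
            transforms.append(RigidTransform.identity())
            used.append(None)
            residuals.append(float("nan"))
            failed.append((i, str(exc)))
    return CoarseResult(fixed_index, transforms, used, residuals, failed)
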