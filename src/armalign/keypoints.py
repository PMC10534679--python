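"""21-slot hand key-point sets: quality scoring, best-sensor selection,
pinhole back-projection to 3D, and slot-index intersection.

Hand landmark detectors emit 21 landmarks in a fixed anatomical order
(slot 0 = wrist, then four slots per finger: thumb 1-4, index 5-8,
middle 9-12, ring 13-16, pinky 17-20), with undetected slots flagged as
missing and one confidence score per image. Registration needs at least
three common landmarks between two poses, so the slot bookkeeping here is
what makes the coarse stage possible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np

from .geometry import CameraIntrinsics

N_SLOTS = 21
MIN_COMMON = 3

__all__ = [
    "N_SLOTS",
    "MIN_COMMON",
    "HandKeyPointSet",
    "KeyPointCorrespondence",
    "SensorSelection",
    "HandLandmarkDetector",
    "detection_quality",
    "select_best_sensor",
    "project_to_3d",
    "intersect_keypoints",
]


@runtime_checkable
class HandLandmarkDetector(Protocol):
    """Adapter contract for an external hand-landmark model.

    Implementations take an RGB image (H, W, 3 uint8 array) and return a 2D
    :class:`HandKeyPointSet` — 21 fixed-order pixel landmarks with missing
    slots flagged and one confidence score for the image. The registration
    core never depends on any particular model; simulated detections satisfy
    the same contract in 3D.
    """

    def __call__(self, image: np.ndarray) -> "HandKeyPointSet": ...


@dataclass
class HandKeyPointSet:
    """Fixed-order 21-slot landmark set (2D pixels or 3D mm).

    Missing slots carry NaN coordinates and ``False`` in ``valid_mask``; the
    two representations are kept consistent at construction.
    """

    coords: np.ndarray  # (21, 2) or (21, 3); NaN where missing
    valid_mask: np.ndarray | None = None
    score: float = 0.0
    sensor_id: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape[0] != N_SLOTS or self.coords.shape[1] not in (2, 3):
            raise ValueError(f"coords must be ({N_SLOTS}, 2) or ({N_SLOTS}, 3)")
        finite = np.isfinite(self.coords).all(axis=1)
        if self.valid_mask is None:
            self.valid_mask = finite
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool).reshape(N_SLOTS)
            if (self.valid_mask & ~finite).any():
                raise ValueError("slot marked valid but has non-finite coordinates")
        self.coords = self.coords.copy()
        self.coords[~self.valid_mask] = np.nan
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")

    @property
    def is_3d(self) -> bool:
        return self.coords.shape[1] == 3

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    @property
    def valid_indices(self) -> np.ndarray:
        return np.flatnonzero(self.valid_mask)

    def barycenter(self) -> np.ndarray:
        """Mean of the valid landmarks (the anchor of the forearm-slicing frame)."""
        if self.n_valid == 0:
            raise ValueError("no valid key points")
        return self.coords[self.valid_mask].mean(axis=0)


@dataclass
class KeyPointCorrespondence:
    """Matched landmark pairs between a fixed and a moving set."""

    indices: np.ndarray  # sorted common slot indices
    fixed: np.ndarray  # (n, 3)
    moving: np.ndarray  # (n, 3)

    @property
    def usable(self) -> bool:
        return len(self.indices) >= MIN_COMMON


@dataclass
class SensorSelection:
    """Outcome of best-sensor selection; ``ok`` is False when an operator must intervene."""

    ok: bool
    sensor_index: int | None = None
    keypoints: HandKeyPointSet | None = None
    reason: str = ""


def detection_quality(kp: HandKeyPointSet) -> float:
    """Detection-quality metric: confidence score times number of valid slots."""
    return kp.score * kp.n_valid


def select_best_sensor(detections, threshold: float = 0.5) -> SensorSelection:
    """Pick, among the three per-pose sensors, the detection maximizing
    ``detection_quality`` among sets with score >= ``threshold`` and at least
    three valid slots. Ties break to the lowest sensor index.

    Returns a failed :class:`SensorSelection` (never raises) when no sensor
    qualifies, signalling that manual registration is needed for this pose.
    """
    detections = list(detections)
    if len(detections) != 3:
        raise ValueError("expected exactly three detection sets")
    best_i, best_q = None, -1.0
    for i, det in enumerate(detections):
        if det is None or det.score < threshold or det.n_valid < MIN_COMMON:
            continue
        q = detection_quality(det)
        if q > best_q:
            best_i, best_q = i, q
    if best_i is None:
        return SensorSelection(False, reason="insufficient key points")
    return SensorSelection(True, best_i, detections[best_i])


def _depth_at(depth: np.ndarray, u: int, v: int) -> float:
    """Depth lookup with a 5x5 median fallback around holes; NaN if unrecoverable."""
    z = depth[v, u]
    if np.isfinite(z) and z > 0:
        return float(z)
    v0, v1 = max(v - 2, 0), min(v + 3, depth.shape[0])
    u0, u1 = max(u - 2, 0), min(u + 3, depth.shape[1])
    patch = depth[v0:v1, u0:u1]
    good = patch[np.isfinite(patch) & (patch > 0)]
    return float(np.median(good)) if good.size else np.nan


def project_to_3d(
    kp2d: HandKeyPointSet, depth: np.ndarray, intrinsics: CameraIntrinsics
) -> HandKeyPointSet:
    """Back-project 2D pixel landmarks through the pinhole model using a depth map.

    X = (u - cx) z / fx, Y = (v - cy) z / fy, Z = z, with z looked up at the
    nearest pixel (median of the valid 5x5 neighborhood as fallback). Slots
    with no recoverable depth become missing.
    """
    if intrinsics is None:
        raise ValueError("camera intrinsics required")
    if kp2d.is_3d:
        raise ValueError("expected a 2D key-point set")
    depth = np.asarray(depth, dtype=float)
    out = np.full((N_SLOTS, 3), np.nan)
    for slot in kp2d.valid_indices:
        u_f, v_f = kp2d.coords[slot]
        u, v = int(round(u_f)), int(round(v_f))
        if not (0 <= u < intrinsics.width and 0 <= v < intrinsics.height):
            continue
        z = _depth_at(depth, u, v)
        if not np.isfinite(z):
            continue
        out[slot] = (
            (u_f - intrinsics.cx) * z / intrinsics.fx,
            (v_f - intrinsics.cy) * z / intrinsics.fy,
            z,
        )
    return HandKeyPointSet(out, score=kp2d.score, sensor_id=kp2d.sensor_id)


def intersect_keypoints(
    fixed: HandKeyPointSet, moving: HandKeyPointSet
) -> KeyPointCorrespondence:
    """Slot-wise intersection of two 3D landmark sets, assembled in slot order."""
    if not (fixed.is_3d and moving.is_3d):
        raise ValueError("both key-point sets must be 3D")
    common = np.flatnonzero(fixed.valid_mask & moving.valid_mask)
    return KeyPointCorrespondence(common, fixed.coords[common], moving.coords[common])
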