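"""Registration quality metrics: common inertia frame, nearest-neighbor
distance maps, and threshold-fraction reports (hand / arm / total)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import PointCloud, RigidTransform, inertia_frame

__all__ = [
    "DistanceReport",
    "DEFAULT_THRESHOLDS",
    "common_inertia_frame",
    "distance_map",
    "report",
]

DEFAULT_THRESHOLDS = (3.0, 5.0, 6.0, 10.0)


@dataclass
class DistanceReport:
    """Summary of per-point nearest-neighbor distances for one region."""

    region: str
    n: int
    mean: float
    std: float
    fractions: dict  # threshold (mm) -> fraction of distances below it

    def to_row(self) -> dict:
        row = {"region": self.region, "n": self.n, "mean_mm": self.mean, "std_mm": self.std}
        for thr, frac in self.fractions.items():
            row[f"frac_lt_{thr:g}mm"] = frac
        return row


def common_inertia_frame(cloud: PointCloud) -> RigidTransform:
    """Transform into the cloud's inertia frame: centroid to the origin, the
    lowest-inertia direction to z, the intermediate one to x."""
    frame = inertia_frame(cloud)
    a0, a1 = frame.axes[0], frame.axes[1]
    rot = np.vstack([a1, np.cross(a0, a1), a0])
    return RigidTransform(rot, -rot @ frame.origin)


def distance_map(test: PointCloud, reference: PointCloud, symmetric: bool = False) -> np.ndarray:
    """Distance from each test point to its nearest reference point.

    With ``symmetric=True`` the reverse-direction distances (reference to
    test) are appended, so summary statistics cover both clouds.
    """
    if len(reference) == 0:
        raise ValueError("empty reference cloud")
    if len(test) == 0:
        raise ValueError("empty test cloud")
    dists, _ = cKDTree(reference.points).query(test.points)
    if symmetric:
        back, _ = cKDTree(test.points).query(reference.points)
        dists = np.concatenate([dists, back])
    return dists


def report(distances, thresholds=DEFAULT_THRESHOLDS, regions=None) -> list:
    """Per-region summaries of a distance map.

    ``regions`` optionally labels each distance (e.g. "hand" / "arm"); a
    "total" report over all points always comes first.
    """
    distances = np.asarray(distances, dtype=float)
    if distances.size == 0:
        raise ValueError("empty distances")

    def summarize(name, d):
        fr = {float(t): float(np.mean(d < t)) for t in thresholds}
        return DistanceReport(name, len(d), float(d.mean()), float(d.std()), fr)

    out = [summarize("total", distances)]
    if regions is not None:
        regions = np.asarray(regions)
        for name in np.unique(regions):
            out.append(summarize(str(name), distances[regions == name]))
    return out
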