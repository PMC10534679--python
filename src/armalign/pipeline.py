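"""End-to-end orchestration: detection -> coarse -> fine -> evaluation.

``run_pipeline`` takes the acquired triplets (one per scanner pose, each with
three co-registered clouds and per-sensor landmark detections) and produces
per-pose rigid transforms into a common frame plus the assembled cloud.
``evaluate_against_truth`` scores a result against the simulator's
ground-truth assembly after mapping both into their common inertia frames.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger("armalign")

from .coarse import CoarseResult, coarse_register_all
from .evaluate import DEFAULT_THRESHOLDS, common_inertia_frame, distance_map, report
from .fine import FineRegConfig, global_fine_register
from .forearm import DegenerateGeometryError, ForearmConfig, detect_forearm_keypoints
from .geometry import PointCloud, RigidTransform, apply_transform, concatenate
from .io import transform_to_json
from .keypoints import select_best_sensor

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "evaluate_against_truth", "save_result"]


@dataclass
class PipelineConfig:
    """All pipeline parameters in one place (see the per-stage configs)."""

    score_threshold: float = 0.5
    w_hand: float = 1.0
    w_fkp: float = 1.0
    forearm: ForearmConfig = field(default_factory=ForearmConfig)
    fine: FineRegConfig = field(default_factory=FineRegConfig)

    @classmethod
    def from_dict(cls, obj: dict) -> "PipelineConfig":
        obj = dict(obj or {})
        forearm = ForearmConfig(**obj.pop("forearm", {}))
        fine = FineRegConfig(**obj.pop("fine", {}))
        return cls(forearm=forearm, fine=fine, **obj)


@dataclass
class PipelineResult:
    fixed_index: int
    coarse: CoarseResult
    fine_transforms: list
    final_transforms: list  # fine o coarse, per pose
    assembled: PointCloud
    fixed_barycenter: np.ndarray | None
    flags: list
    log: list


def run_pipeline(triplets, config: PipelineConfig | None = None) -> PipelineResult:
    """Run detection, coarse and global fine registration on a list of triplets.

    Stage failures are flagged (machine-readable) rather than raised; a pose
    without usable landmarks keeps an identity coarse transform and is still
    carried through the fine stage.
    """
    config = config or PipelineConfig()
    flags = []

    log = []

    def note(msg):
        log.append(msg)
        logger.info(msg)

    merged = [t.merged() for t in triplets]

    best_kps, fkps = [], []
    for t, cloud in zip(triplets, merged):
        sel = select_best_sensor(t.detections, config.score_threshold)
        if not sel.ok:
            flags.append(("detection_failed", t.pose_id, sel.reason))
            best_kps.append(None)
            fkps.append(None)
            continue
        best_kps.append(sel.keypoints)
        note(f"pose {t.pose_id}: sensor {sel.sensor_index}, "
             f"{sel.keypoints.n_valid} valid slots")
        try:
            fkp, _, _ = detect_forearm_keypoints(
                cloud, sel.keypoints.barycenter(), config.forearm
            )
            fkps.append(fkp)
        except DegenerateGeometryError as exc:
            flags.append(("forearm_failed", t.pose_id, str(exc)))
            fkps.append(None)

    coarse = coarse_register_all(best_kps, fkps, config.w_hand, config.w_fkp)
    note(f"fixed triplet: {coarse.fixed_index}")
    for i, reason in coarse.failed:
        flags.append(("coarse_failed", triplets[i].pose_id, reason))

    coarse_aligned = [apply_transform(tr, c) for tr, c in zip(coarse.transforms, merged)]
    fine_transforms, fine_flags = global_fine_register(coarse_aligned, config.fine)
    for epoch, k, flag in fine_flags:
        flags.append(("fine_pair_flag", triplets[k].pose_id, f"epoch {epoch}: {flag}"))

    final = [f.compose(c) for f, c in zip(fine_transforms, coarse.transforms)]
    assembled = concatenate(
        apply_transform(tr, c) for tr, c in zip(final, merged)
    )
    barycenter = None
    if best_kps[coarse.fixed_index] is not None:
        barycenter = final[coarse.fixed_index].transform_points(
            best_kps[coarse.fixed_index].coords[best_kps[coarse.fixed_index].valid_mask]
        ).mean(axis=0)
    return PipelineResult(
        coarse.fixed_index, coarse, fine_transforms, final, assembled, barycenter, flags, log
    )


def _strip(cloud: PointCloud) -> PointCloud:
    return PointCloud(cloud.points)


def evaluate_against_truth(
    triplets, result: PipelineResult, thresholds=DEFAULT_THRESHOLDS
):
    """Distance reports of the automatic assembly against the ground-truth one.

    Both assemblies (identical point sets under different transforms) are
    mapped into their own common inertia frames — centroid at the origin,
    lowest-inertia axis to z, intermediate to x — before measuring
    nearest-neighbor distances, so the comparison is invariant to the global
    pose of either result. Points are split into hand/arm regions at the
    hand-landmark barycenter plane when the barycenter is known.
    """
    merged = [t.merged() for t in triplets]
    estimated = concatenate(
        apply_transform(tr, c) for tr, c in zip(result.final_transforms, merged)
    )
    reference = concatenate(
        apply_transform(t.truth_transform, c) for t, c in zip(triplets, merged)
    )
    est_frame = common_inertia_frame(estimated)
    ref_frame = common_inertia_frame(reference)
    est_c = apply_transform(est_frame, _strip(estimated))
    ref_c = apply_transform(ref_frame, _strip(reference))
    distances = distance_map(est_c, ref_c)
    regions = None
    if result.fixed_barycenter is not None:
        z_split = est_frame.transform_points(result.fixed_barycenter[None])[0, 2]
        # the barycenter plane sits mid-hand; offset down to the wrist region
        regions = np.where(est_c.points[:, 2] > z_split - 100.0, "hand", "arm")
    return report(distances, thresholds, regions), distances


def save_result(out_dir, result: PipelineResult, reports=None) -> None:
    """Write transforms, flags and (optionally) distance reports as JSON/CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "fixed_index": result.fixed_index,
        "coarse": [transform_to_json(t, f"pose_{i}", "fixed") for i, t in enumerate(result.coarse.transforms)],
        "fine": [transform_to_json(t) for t in result.fine_transforms],
        "final": [transform_to_json(t, f"pose_{i}", "registered") for i, t in enumerate(result.final_transforms)],
        "residual_rms_mm": result.coarse.residual_rms,
        "flags": [list(f) for f in result.flags],
        "log": result.log,
    }
    (out_dir / "transforms.json").write_text(json.dumps(payload, indent=1))
    if reports:
        lines = ["region,n,mean_mm,std_mm," + ",".join(
            f"frac_lt_{t:g}mm" for t in sorted(reports[0].fractions)
        )]
        for rep in reports:
            fr = ",".join(f"{rep.fractions[t]:.6f}" for t in sorted(rep.fractions))
            lines.append(f"{rep.region},{rep.n},{rep.mean:.6f},{rep.std:.6f},{fr}")
        (out_dir / "report.csv").write_text("\n".join(lines) + "\n")
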