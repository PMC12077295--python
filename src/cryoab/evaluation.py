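"""Matching predictions to ground truth and computing detection metrics.

Predicted and true antibody centers are paired by minimum-total-distance
assignment (Hungarian algorithm); pairs closer than a 10 Å threshold are
true positives.  Metrics follow the two aggregation conventions: ``ab``
pools TP/FP/FN over all antibodies, ``sys`` averages per-system F1 so a
system with many antibodies does not dominate.  For matched pairs we also
report center distances, angular errors of the direction and in-plane-angle
decomposition, and the RMSD between the two template placements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .codec import AbPose
from .template import TemplateStructure

TP_THRESHOLD = 10.0  # Å


@dataclass
class MatchResult:
    pairs: list[tuple[int, int, float]]  # (prediction idx, truth idx, distance Å)
    tp: int
    fp: int
    fn: int
    n_pred: int
    n_gt: int
    angle_errors: list[tuple[float, float]] = field(default_factory=list)
    rmsds: list[float] = field(default_factory=list)

    @property
    def f1(self) -> float:
        if self.n_gt == 0 and self.n_pred == 0:
            return 1.0  # empty system, no prediction: perfect true negative
        denom = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / denom if denom else 0.0


def match(
    pred_centers, gt_centers, tp_threshold: float = TP_THRESHOLD
) -> MatchResult:
    """Hungarian assignment of centers, thresholded at ``tp_threshold`` Å.

    Assignment minimizes total distance over the rectangular matrix first;
    the threshold is applied afterwards, so a matched-but-distant pair
    counts as one false positive plus one false negative.
    """
    pred = np.atleast_2d(np.asarray(pred_centers, float)) if len(pred_centers) else np.zeros((0, 3))
    gt = np.atleast_2d(np.asarray(gt_centers, float)) if len(gt_centers) else np.zeros((0, 3))
    n_pred, n_gt = len(pred), len(gt)
    pairs: list[tuple[int, int, float]] = []
    if n_pred and n_gt:
        dist = np.linalg.norm(pred[:, None, :] - gt[None, :, :], axis=2)
        rows, cols = linear_sum_assignment(dist)
        pairs = [(int(r), int(c), float(dist[r, c])) for r, c in zip(rows, cols)]
    tp = sum(1 for _, _, d in pairs if d < tp_threshold)
    return MatchResult(
        pairs=pairs,
        tp=tp,
        fp=n_pred - tp,
        fn=n_gt - tp,
        n_pred=n_pred,
        n_gt=n_gt,
    )


def f1_scores(results: list[MatchResult]) -> dict[str, float]:
    """Pooled (ab) and per-system-averaged (sys) F1, recall and precision.

    ``f1_ab`` pools TP/FP/FN over every antibody in every system; ``f1_sys``
    averages each system's own F1.  All values are percentages.
    """
    if not results:
        raise ValueError("need at least one system")
    tp = sum(r.tp for r in results)
    fp = sum(r.fp for r in results)
    fn = sum(r.fn for r in results)
    f1_ab = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 1.0
    recall = tp / (tp + fn) if (tp + fn) else 1.0
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    f1_sys = float(np.mean([r.f1 for r in results]))
    return {
        "f1_ab": 100.0 * f1_ab,
        "f1_sys": 100.0 * f1_sys,
        "recall": 100.0 * recall,
        "precision": 100.0 * precision,
    }


def angular_errors(pred_pose: AbPose, gt_pose: AbPose) -> tuple[float, float]:
    """(direction error, in-plane-angle error) of a matched pair, degrees.

    Direction error is the angle between the two ``p`` axes; the in-plane
    error is the wrapped absolute difference of ``theta`` mapped to
    [0°, 180°].
    """
    p_pred, theta_pred = pred_pose.direction, pred_pose.angle
    p_gt, theta_gt = gt_pose.direction, gt_pose.angle
    cosang = float(np.clip(np.dot(p_pred, p_gt), -1.0, 1.0))
    dir_err = float(np.degrees(np.arccos(cosang)))
    dtheta = np.degrees(theta_pred - theta_gt)
    dtheta = abs((dtheta + 180.0) % 360.0 - 180.0)
    return dir_err, float(dtheta)


def placement_rmsd(
    pred_pose: AbPose, gt_pose: AbPose, template: TemplateStructure
) -> float:
    """RMSD between the template placed by the two poses (no re-superposition)."""
    a = template.transformed(pred_pose.rotation, pred_pose.translation)
    b = template.transformed(gt_pose.rotation, gt_pose.translation)
    return float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))


def evaluate_system(
    pred_poses: list[AbPose],
    gt_poses: list[AbPose],
    templates: dict[str, TemplateStructure] | None = None,
    tp_threshold: float = TP_THRESHOLD,
) -> MatchResult:
    """Match one system's predictions to its ground truth, with pose metrics."""
    result = match(
        [p.translation for p in pred_poses],
        [p.translation for p in gt_poses],
        tp_threshold,
    )
    for pi, gi, d in result.pairs:
        if d >= tp_threshold:
            continue
        result.angle_errors.append(angular_errors(pred_poses[pi], gt_poses[gi]))
        if templates is not None:
            result.rmsds.append(
                placement_rmsd(
                    pred_poses[pi], gt_poses[gi], templates[gt_poses[gi].ab_class]
                )
            )
    return result


def report_table(results: list[MatchResult]) -> pd.DataFrame:
    """One row per system: counts and mean metrics over its matched pairs."""
    rows = []
    for i, r in enumerate(results):
        matched = [d for _, _, d in r.pairs if d < TP_THRESHOLD]
        rows.append(
            {
                "system": i,
                "n_gt": r.n_gt,
                "n_pred": r.n_pred,
                "tp": r.tp,
                "fp": r.fp,
                "fn": r.fn,
                "f1": round(100 * r.f1, 2),
                "mean_distance": round(float(np.mean(matched)), 3) if matched else np.nan,
                "mean_rmsd": round(float(np.mean(r.rmsds)), 3) if r.rmsds else np.nan,
                "mean_dir_err_deg": round(float(np.mean([a for a, _ in r.angle_errors])), 2)
                if r.angle_errors
                else np.nan,
                "mean_theta_err_deg": round(float(np.mean([t for _, t in r.angle_errors])), 2)
                if r.angle_errors
                else np.nan,
            }
        )
    return pd.DataFrame(rows)


def summary(results: list[MatchResult]) -> dict[str, float]:
    """Corpus-level metrics: F1s plus mean distance/RMSD/angles over TPs."""
    out = f1_scores(results)
    dists = [d for r in results for _, _, d in r.pairs if d < TP_THRESHOLD]
    rmsds = [v for r in results for v in r.rmsds]
    dirs = [a for r in results for a, _ in r.angle_errors]
    thetas = [t for r in results for _, t in r.angle_errors]
    out["mean_distance"] = float(np.mean(dists)) if dists else float("nan")
    out["mean_rmsd"] = float(np.mean(rmsds)) if rmsds else float("nan")
    out["mean_direction_error_deg"] = float(np.mean(dirs)) if dirs else float("nan")
    out["mean_theta_error_deg"] = float(np.mean(thetas)) if thetas else float("nan")
    return out
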