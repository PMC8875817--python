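"""Comparison of tracked output against a reference (e.g. motion capture).

The tracker reports poses in its model frame while a reference system reports
them in its own marker frame; a rigid calibration transform between the two is
estimated from the first ``n_calib`` frames of a static standing recording:
the translation is the arithmetic mean of the per-frame translation offsets
and the rotation is the eigenvector quaternion average (the normalized
principal eigenvector of the 4×4 accumulation matrix Q·Qᵀ) of the per-frame
relative rotations.

Pose error is split into a rotational part (the minimum angle between the two
orientations, degrees) and a translational part (Euclidean distance, mm).

Gait-cycle detection is scored with precision, recall and an F1 defined as the
arithmetic mean ``0.5·(precision + recall)``; the conventional harmonic-mean
F1 is available separately as :func:`f1_harmonic`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .gait import GaitCycle
from .geometry import (
    angular_distance,
    average_quaternion,
    quat_wxyz_to_rotation,
    rotation_to_quat_wxyz,
)

__all__ = [
    "CalibrationTransform",
    "DetectionCounts",
    "calibrate",
    "apply_calibration",
    "pose_errors",
    "detection_metrics",
    "f1_harmonic",
    "match_cycles",
]


@dataclass(frozen=True)
class CalibrationTransform:
    """Rigid transform mapping tracker poses into the reference frame."""

    rotation: np.ndarray  # unit quaternion (w, x, y, z)
    translation: np.ndarray  # mm
    n_calib: int


@dataclass(frozen=True)
class DetectionCounts:
    TP: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative integers")


def calibrate(
    quats_tracker: np.ndarray,
    trans_tracker: np.ndarray,
    quats_reference: np.ndarray,
    trans_reference: np.ndarray,
    n_calib: int,
) -> CalibrationTransform:
    """Estimate the tracker→reference transform from static calibration frames.

    Quaternions are (N, 4) in (w, x, y, z); translations (N, 3) in mm.  The
    per-frame relative rotation is ``R_ref · R_trkᵀ``; relative rotations are
    averaged with the eigenvector quaternion mean, then the translation is the
    arithmetic mean of ``t_ref − R_cal·t_trk`` over the same frames.
    """
    qt = np.atleast_2d(np.asarray(quats_tracker, dtype=float))[:n_calib]
    qr = np.atleast_2d(np.asarray(quats_reference, dtype=float))[:n_calib]
    tt = np.atleast_2d(np.asarray(trans_tracker, dtype=float))[:n_calib]
    tr = np.atleast_2d(np.asarray(trans_reference, dtype=float))[:n_calib]
    if len(qt) == 0 or len(qt) != len(qr) or len(tt) != len(tr) or len(qt) < 1:
        raise ValueError("need at least one common calibration frame")
    if n_calib > len(quats_tracker) or n_calib > len(quats_reference):
        raise ValueError("n_calib exceeds stream length")

    rel = []
    for a, b in zip(qt, qr):
        r = quat_wxyz_to_rotation(b).as_matrix() @ quat_wxyz_to_rotation(a).as_matrix().T
        rel.append(rotation_to_quat_wxyz(r))
    q_cal = average_quaternion(np.array(rel))
    r_cal = quat_wxyz_to_rotation(q_cal).as_matrix()
    t_cal = (tr - tt @ r_cal.T).mean(axis=0)
    return CalibrationTransform(rotation=q_cal, translation=t_cal, n_calib=len(qt))


def apply_calibration(
    cal: CalibrationTransform, quats: np.ndarray, trans: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Map tracker pose streams into the reference frame."""
    r_cal = quat_wxyz_to_rotation(cal.rotation).as_matrix()
    quats = np.atleast_2d(np.asarray(quats, dtype=float))
    trans = np.atleast_2d(np.asarray(trans, dtype=float))
    q_out = np.array(
        [
            rotation_to_quat_wxyz(r_cal @ quat_wxyz_to_rotation(q).as_matrix())
            for q in quats
        ]
    )
    t_out = trans @ r_cal.T + cal.translation
    return q_out, t_out


def pose_errors(
    quat_a: np.ndarray, trans_a: np.ndarray, quat_b: np.ndarray, trans_b: np.ndarray
) -> Tuple[float, float]:
    """(rotational error in degrees, translational error in mm)."""
    rot = np.degrees(angular_distance(np.asarray(quat_a), np.asarray(quat_b)))
    tr = float(np.linalg.norm(np.asarray(trans_a) - np.asarray(trans_b)))
    return float(rot), tr


def detection_metrics(counts: DetectionCounts) -> Tuple[float, float, float]:
    """Precision, recall and the arithmetic-mean F1 ``0.5·(P + R)``."""
    if counts.TP + counts.FP == 0 or counts.TP + counts.FN == 0:
        raise ZeroDivisionError("precision/recall undefined for zero denominators")
    precision = counts.TP / (counts.TP + counts.FP)
    recall = counts.TP / (counts.TP + counts.FN)
    return precision, recall, 0.5 * (precision + recall)


def f1_harmonic(counts: DetectionCounts) -> float:
    """Conventional harmonic-mean F1 (not the arithmetic-mean variant)."""
    p, r, _ = detection_metrics(counts)
    if p + r == 0:
        return 0.0
    return 2 * p * r / (p + r)


_PARAMS = (
    ("step_length", "step_length", "mm"),
    ("step_width", "step_width", "mm"),
    ("cycle_time", "cycle_time", "s"),
    ("stance_time", "stance_time", "s"),
    ("swing_time", "swing_time", "s"),
)


def match_cycles(
    cycles_pred: Sequence[GaitCycle],
    cycles_truth: Sequence[GaitCycle],
    tolerance_s: Optional[float] = None,
) -> Tuple[DetectionCounts, pd.DataFrame]:
    """Greedy one-to-one matching of predicted to reference gait cycles.

    Cycles are matched by proximity of their terminating heel-strike time
    within ``tolerance_s`` (default: half the median truth cycle time).
    Unmatched predictions count as false positives, unmatched truths as false
    negatives.  Matched pairs yield absolute errors for the five gait
    parameters plus HS/TO timing errors, and percentage errors
    ``(measured − true)/true × 100`` per parameter.
    """
    preds = sorted(cycles_pred, key=lambda c: c.hs_end.time)
    truths = sorted(cycles_truth, key=lambda c: c.hs_end.time)
    if tolerance_s is None:
        tolerance_s = (
            0.5 * float(np.median([c.cycle_time for c in truths])) if truths else 0.5
        )

    used = set()
    rows = []
    tp = 0
    for p in preds:
        best_j, best_d = None, np.inf
        for j, t in enumerate(truths):
            if j in used or t.side != p.side:
                continue
            d = abs(p.hs_end.time - t.hs_end.time)
            if d < best_d:
                best_j, best_d = j, d
        if best_j is not None and best_d <= tolerance_s:
            used.add(best_j)
            tp += 1
            t = truths[best_j]
            row = {
                "side": p.side,
                "hs_time_error_s": p.hs_end.time - t.hs_end.time,
                "to_time_error_s": p.to.time - t.to.time,
            }
            for name, attr, _unit in _PARAMS:
                mv = getattr(p, attr) if not name.startswith("step") else getattr(p, name)
                tv = getattr(t, attr) if not name.startswith("step") else getattr(t, name)
                row[f"{name}_error"] = mv - tv
                row[f"{name}_pct_error"] = (
                    (mv - tv) / tv * 100.0 if tv not in (0.0,) else np.nan
                )
            rows.append(row)
    counts = DetectionCounts(TP=tp, FP=len(preds) - tp, FN=len(truths) - tp)
    return counts, pd.DataFrame(rows)
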