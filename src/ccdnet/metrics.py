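"""Classifier evaluation and the double-integration depth baseline.

Class 1 ("correct compression") is the positive class throughout: TP counts
correct compressions classified as correct, FP abnormal ones classified as
correct, and so on.  The ROC curve is built by a descending threshold sweep
over the class-1 scores and its area equals the normalized Mann-Whitney U
statistic.

``integrate_depth`` is the traditional alternative the classifier replaces:
twice integrating the baseline-removed acceleration of one compression and
taking the peak displacement magnitude as the depth.  It is exact for clean
signals but degrades under drift, since integration accumulates
low-frequency error quadratically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .segment import PulseSegment
from .simulate import depth_to_label

__all__ = [
    "ConfusionCounts",
    "ROCCurve",
    "confusion",
    "accuracy",
    "f_score",
    "roc_auc",
    "integrate_depth",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN tallies with class 1 as positive."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class ROCCurve:
    """Threshold sweep of (FPR, TPR) points with trapezoidal area."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def confusion(predicted, actual) -> ConfusionCounts:
    """Tally a binary confusion matrix (class 1 positive)."""
    pred = np.asarray(predicted)
    act = np.asarray(actual)
    if pred.shape != act.shape:
        raise ValueError("predicted and actual must have equal length")
    if not (np.isin(pred, (0, 1)).all() and np.isin(act, (0, 1)).all()):
        raise ValueError("labels must be 0 or 1")
    return ConfusionCounts(
        TP=int(np.sum((pred == 1) & (act == 1))),
        TN=int(np.sum((pred == 0) & (act == 0))),
        FP=int(np.sum((pred == 1) & (act == 0))),
        FN=int(np.sum((pred == 0) & (act == 1))),
    )


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    if c.total < 1:
        raise ValueError("empty confusion counts")
    return (c.TP + c.TN) / c.total


def f_score(c: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall; 0 when there are no TP."""
    if c.TP + c.FP < 1 and c.TP + c.FN < 1:
        logger.warning("f_score: no positives anywhere; returning 0 by convention")
        return 0.0
    if c.TP == 0:
        return 0.0
    precision = c.TP / (c.TP + c.FP)
    recall = c.TP / (c.TP + c.FN)
    return 2.0 * precision * recall / (precision + recall)


def roc_auc(scores, actual) -> ROCCurve:
    """ROC curve and AUC from class-1 scores.

    The curve is swept over the unique scores in descending order (prefixed
    with +inf so it starts at (0, 0)); the area is the trapezoidal integral
    over FPR and equals the tie-corrected normalized U statistic.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(actual)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for a ROC curve")

    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    y_sorted = y[order]
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], len(s_sorted) - 1]
    tp = np.cumsum(y_sorted == 1)[distinct]
    fp = np.cumsum(y_sorted == 0)[distinct]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def integrate_depth(
    seg: PulseSegment, dt: float, baseline: float | None = None
) -> tuple[float, int]:
    """Depth estimate by trapezoidal double integration of one compression.

    The baseline (explicit argument, else the segment's recorded static
    gravity, else 0) is removed; the residual acceleration is integrated to
    velocity and again to displacement, both starting from rest; the peak
    displacement magnitude over the segment, in millimetres, is the depth.

    Returns
    -------
    (depth_mm, label) where the label applies the 50-60 mm correctness band
    (0 for a degenerate zero depth).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if len(seg) < 3:
        raise ValueError("segment too short to integrate")
    if baseline is None:
        baseline = seg.baseline if seg.baseline is not None else 0.0
    a = seg.samples - baseline
    v = cumulative_trapezoid(a, dx=dt, initial=0.0)
    x = cumulative_trapezoid(v, dx=dt, initial=0.0)
    depth_mm = float(np.max(np.abs(x)) * 1000.0)
    label = 0 if depth_mm <= 0 else depth_to_label(depth_mm)
    return depth_mm, label
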