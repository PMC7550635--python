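"""Classification performance metrics and the DeLong test for paired AUCs.

Accuracy = (TP + TN) / (TP + FP + TN + FN), sensitivity = TP / (TP + FN)
(recall on the patient-like positive class), specificity = TN / (TN + FP).
AUC is the Mann–Whitney probability of ranking a random positive above a
random negative, ties counted 1/2; correlated AUCs computed on the same
subjects are compared with DeLong's placement-value covariance estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "confusion_counts",
    "PerformanceMetrics",
    "performance_metrics",
    "mann_whitney_auc",
    "DeLongComparison",
    "delong_test",
]


def confusion_counts(y_true, y_pred, positive=1) -> tuple[int, int, int, int]:
    """(TP, FN, TN, FP) with the given positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == positive
    tp = int(((y_pred == positive) & pos).sum())
    fn = int(((y_pred != positive) & pos).sum())
    tn = int(((y_pred != positive) & ~pos).sum())
    fp = int(((y_pred == positive) & ~pos).sum())
    return tp, fn, tn, fp


@dataclass
class PerformanceMetrics:
    tp: int
    fn: int
    tn: int
    fp: int
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float | None = None


def performance_metrics(tp: int, fn: int, tn: int, fp: int, auc: float | None = None) -> PerformanceMetrics:
    """Apply the confusion-count formulas; zero denominators yield NaN."""
    total = tp + fp + tn + fn
    acc = (tp + tn) / total if total else float("nan")
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return PerformanceMetrics(tp, fn, tn, fp, acc, sens, spec, auc)


def mann_whitney_auc(scores, y, positive=1) -> float:
    """Rank-statistic AUC with ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    pos = scores[y == positive]
    neg = scores[y != positive]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes required for AUC")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    return float((ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg)))


def _placements(scores: np.ndarray, m: int) -> tuple[float, np.ndarray, np.ndarray]:
    """Fast-DeLong placement values; first m entries of ``scores`` are the
    positives.  Returns (auc, V10 over positives, V01 over negatives)."""
    n = scores.size - m
    tx = stats.rankdata(scores[:m])
    ty = stats.rankdata(scores[m:])
    tz = stats.rankdata(scores)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    auc = float(v10.mean())
    return auc, v10, v01


@dataclass
class DeLongComparison:
    auc1: float
    auc2: float
    var_diff: float
    z: float
    p: float


def delong_test(scores1, scores2, y, positive=1) -> DeLongComparison:
    """Two-sided DeLong comparison of two correlated ROC AUCs.

    Both score vectors must be computed on the same subjects.  Identical
    score vectors return z = 0, p = 1 by convention; a zero variance with
    unequal AUCs is an error.
    """
    s1 = np.asarray(scores1, dtype=float)
    s2 = np.asarray(scores2, dtype=float)
    y = np.asarray(y)
    if s1.shape != s2.shape or s1.shape[0] != y.shape[0]:
        raise ValueError("score vectors and labels must share the subject axis")
    pos = y == positive
    m, n = int(pos.sum()), int((~pos).sum())
    if m == 0 or n == 0:
        raise ValueError("both classes required")
    order = np.concatenate([np.flatnonzero(pos), np.flatnonzero(~pos)])
    a1, v10_1, v01_1 = _placements(s1[order], m)
    a2, v10_2, v01_2 = _placements(s2[order], m)
    if np.array_equal(s1, s2):
        return DeLongComparison(a1, a2, 0.0, 0.0, 1.0)
    s10 = np.cov(np.vstack([v10_1, v10_2]))
    s01 = np.cov(np.vstack([v01_1, v01_2]))
    cov = s10 / m + s01 / n
    var = float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
    if var <= 0:
        if abs(a1 - a2) < 1e-12:
            return DeLongComparison(a1, a2, 0.0, 0.0, 1.0)
        raise ValueError("zero DeLong variance with unequal AUCs")
    z = (a1 - a2) / np.sqrt(var)
    p = float(2 * stats.norm.sf(abs(z)))
    return DeLongComparison(a1, a2, var, float(z), p)
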