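"""Discriminative feature selection: edge-wise t-tests and grouped rankings.

Connections are screened by pooled-variance two-sample Student's t-tests on
the training subjects only (p < alpha, default 0.05, uncorrected — the edge
screen is a per-fold filter, not an inference); edges surviving in every
cross-validation fold form the consensus connection set reported as the
biomarker.  Nodal graph-metric features are selected jointly per ROI by
group-LASSO (see :mod:`connectomeclf.grouplasso`); ROIs are ranked by group
norm and individual features by absolute weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import reduce

import numpy as np

from .grouplasso import GroupLassoLogistic

__all__ = [
    "EdgeSelection",
    "edge_ttest_select",
    "consensus_edges",
    "fisher_rz",
    "select_groups",
    "nodal_group_ids",
]


@dataclass
class EdgeSelection:
    """Per-edge two-sample t statistics and the selected index set."""

    t: np.ndarray
    p: np.ndarray
    selected: np.ndarray  # sorted edge indices with p < alpha
    alpha: float


def _pooled_ttest(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized pooled-variance two-sample t over feature columns."""
    from scipy import stats

    n1, n2 = a.shape[0], b.shape[0]
    v1 = a.var(axis=0, ddof=1)
    v2 = b.var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / denom
    df = n1 + n2 - 2
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, p


def fisher_rz(r: np.ndarray, clip: float = 0.999999) -> np.ndarray:
    """Fisher r-to-z variance-stabilizing transform for correlation weights."""
    return np.arctanh(np.clip(r, -clip, clip))


def edge_ttest_select(
    edge_table: np.ndarray,
    y: np.ndarray,
    train_idx=None,
    alpha: float = 0.05,
    fisher: bool = False,
) -> EdgeSelection:
    """Two-sample t-test per edge on training rows only; select p < alpha.

    ``edge_table`` is subjects x M (upper-triangle edge weights); ``y`` holds
    +1/-1 labels.  Edges with zero pooled variance are excluded with a
    warning (their t statistic is undefined).
    """
    X = np.asarray(edge_table, dtype=float)
    y = np.asarray(y)
    if train_idx is None:
        train_idx = np.arange(X.shape[0])
    Xt, yt = X[train_idx], y[train_idx]
    if fisher:
        Xt = fisher_rz(Xt)
    a, b = Xt[yt > 0], Xt[yt < 0]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two training subjects per group")
    t, p = _pooled_ttest(a, b)
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} edges with zero pooled variance excluded",
            UserWarning,
        )
        t = np.where(degenerate, 0.0, t)
        p = np.where(degenerate, 1.0, p)
    selected = np.flatnonzero(p < alpha)
    return EdgeSelection(t=t, p=p, selected=selected, alpha=alpha)


def consensus_edges(per_fold_selections) -> np.ndarray:
    """Edge indices selected in every fold (set intersection)."""
    sets = [set(np.asarray(s).tolist()) for s in per_fold_selections]
    if not sets:
        raise ValueError("need at least one fold")
    consensus = reduce(set.intersection, sets)
    if not consensus:
        warnings.warn("empty consensus edge set", UserWarning)
    return np.array(sorted(consensus), dtype=int)


def nodal_group_ids(n_roi: int, n_metrics: int = 6) -> np.ndarray:
    """Group label per column of a subjects x (n_roi * n_metrics) nodal
    feature table laid out ROI-major (ROI 0 metrics, ROI 1 metrics, ...)."""
    return np.repeat(np.arange(n_roi), n_metrics)


def select_groups(model: GroupLassoLogistic, top_k: int = 20):
    """Rank ROIs by group norm and (ROI, metric) features by |weight|.

    Returns (roi_ranking, feature_ranking): lists of (roi, norm) and
    (roi, metric_index, weight) truncated to the nonzero entries, at most
    ``top_k`` each.
    """
    norms = model.group_norms_
    nonzero = [(g, v) for g, v in sorted(norms.items()) if v > 0]
    if not nonzero:
        warnings.warn("all group weights are zero; nothing to rank", UserWarning)
        return [], []
    roi_rank = sorted(nonzero, key=lambda gv: (-gv[1], gv[0]))[:top_k]
    feats = []
    gid = model.group_ids_
    for col, w in enumerate(model.coef_):
        if w != 0.0:
            g = gid[col]
            metric_idx = int(np.flatnonzero(np.flatnonzero(gid == g) == col)[0])
            feats.append((int(g), metric_idx, float(w)))
    feat_rank = sorted(feats, key=lambda t: (-abs(t[2]), t[0], t[1]))[:top_k]
    return roi_rank, feat_rank
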