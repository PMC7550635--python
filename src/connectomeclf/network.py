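"""From ROI time series to nonnegative Pearson networks and binary graphs.

Edges are Pearson correlations between regional signals; negative
correlations are set to zero before any thresholding, and binary undirected
networks are obtained by retaining the top fraction (sparsity) of the
N(N-1)/2 candidate edges across a grid of sparsity values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

__all__ = [
    "SparsityGrid",
    "preprocess_timeseries",
    "compute_connectivity",
    "binarize_at_sparsity",
    "threshold_series",
    "edge_vector",
    "edge_index_pairs",
    "n_edges",
]


@dataclass(frozen=True)
class SparsityGrid:
    """Evenly spaced sparsity thresholds; the default 0.02..0.5 step 0.01
    grid has exactly 49 values."""

    s_min: float = 0.02
    s_max: float = 0.5
    step: float = 0.01

    def __post_init__(self):
        if not (0 < self.s_min <= self.s_max <= 1):
            raise ValueError("sparsity thresholds must lie in (0, 1]")
        if self.step <= 0:
            raise ValueError("step must be positive")

    @property
    def thresholds(self) -> np.ndarray:
        n = int(round((self.s_max - self.s_min) / self.step))
        vals = np.round(self.s_min + self.step * np.arange(n + 1), 10)
        return vals[vals <= self.s_max + 1e-12]

    def __len__(self) -> int:
        return len(self.thresholds)

    def __iter__(self):
        return iter(self.thresholds)


def preprocess_timeseries(
    values: np.ndarray,
    detrend: bool = False,
    band: tuple[float, float] | None = None,
    tr: float = 2.0,
) -> np.ndarray:
    """Optional per-column linear detrend and zero-phase band-pass filter.

    ``band`` is (low, high) in Hz; ``tr`` is the sampling interval in
    seconds.  Both steps default to off — synthetic cohorts need neither.
    """
    x = np.asarray(values, dtype=float)
    if detrend:
        x = _signal.detrend(x, axis=0, type="linear")
    if band is not None:
        if tr <= 0:
            raise ValueError("tr must be positive")
        nyquist = 0.5 / tr
        low, high = band
        if not (0 <= low < high < nyquist):
            raise ValueError(f"band {band} must satisfy 0 <= low < high < Nyquist ({nyquist} Hz)")
        sos = _signal.butter(4, [max(low, 1e-6), high], btype="bandpass", fs=1.0 / tr, output="sos")
        x = _signal.sosfiltfilt(sos, x, axis=0)
    return x


def compute_connectivity(values: np.ndarray, roi_names: list[str] | None = None) -> np.ndarray:
    """Pearson correlation of every ROI pair, negatives zeroed, zero diagonal.

    Raises when a column has zero variance, naming the offending ROI.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("time series must be a T x N matrix with T >= 3")
    if not np.all(np.isfinite(x)):
        raise ValueError("time series contains non-finite values")
    sd = x.std(axis=0)
    bad = np.where(sd == 0)[0]
    if bad.size:
        name = roi_names[bad[0]] if roi_names else f"column {bad[0]}"
        raise ValueError(f"zero-variance ROI: {name}")
    r = np.corrcoef(x, rowvar=False)
    r = np.clip(r, 0.0, 1.0)  # negatives zeroed per the positive-correlation restriction
    np.fill_diagonal(r, 0.0)
    return (r + r.T) / 2.0


def n_edges(n_roi: int) -> int:
    return n_roi * (n_roi - 1) // 2


def edge_index_pairs(n_roi: int) -> np.ndarray:
    """Row-major upper-triangle (i, j) pairs, i < j; the canonical edge order."""
    iu = np.triu_indices(n_roi, k=1)
    return np.column_stack(iu)


def edge_vector(weights: np.ndarray) -> np.ndarray:
    """Flatten a symmetric matrix to its M = N(N-1)/2 upper-triangle entries."""
    iu = np.triu_indices(weights.shape[0], k=1)
    return np.asarray(weights, dtype=float)[iu]


def _edge_order(weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Candidate edges sorted by descending weight with lexicographic (i, j)
    tie-break; returns (order, edge weights) in canonical edge-vector order."""
    w = edge_vector(weights)
    order = np.lexsort((np.arange(w.size), -w))  # stable: -w primary, index secondary
    return order, w


def binarize_at_sparsity(weights: np.ndarray, s: float) -> np.ndarray:
    """Binary adjacency retaining the round(s * M) strongest positive edges."""
    if not (0 < s <= 1):
        raise ValueError(f"sparsity {s} outside (0, 1]")
    return threshold_series(weights, [s])[0]


def threshold_series(weights: np.ndarray, grid) -> list[np.ndarray]:
    """One binary graph per sparsity threshold; edge sets are nested in s.

    The target edge count at sparsity s is k = round(s * M) with half-up
    rounding; ties at the cutoff weight break by lexicographic edge index.
    If fewer than k edges have positive weight, all positive edges are kept
    and a warning is issued.
    """
    weights = np.asarray(weights, dtype=float)
    n = weights.shape[0]
    m = n_edges(n)
    order, w = _edge_order(weights)
    n_positive = int((w > 0).sum())
    iu = np.triu_indices(n, k=1)
    graphs = []
    for s in grid:
        if not (0 < s <= 1):
            raise ValueError(f"sparsity {s} outside (0, 1]")
        k = int(np.floor(s * m + 0.5))  # round half-up
        if k > n_positive:
            warnings.warn(
                f"sparsity {s}: only {n_positive} positive edges available for "
                f"target {k}; keeping all positive edges",
                UserWarning,
                stacklevel=2,
            )
            k = n_positive
        adj = np.zeros((n, n), dtype=np.int8)
        keep = order[:k]
        adj[iu[0][keep], iu[1][keep]] = 1
        adj |= adj.T
        graphs.append(adj)
    return graphs
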