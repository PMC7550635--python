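"""Cohort-level featurization: edges, global AUCs and nodal AUCs per subject.

The three feature modalities fed to the classifier:

* **C** — the M = N(N-1)/2 nonnegative Pearson edge weights;
* **G** — the 7 global graph metrics summed over the sparsity grid;
* **N** — the N x 6 nodal graph metrics summed over the sparsity grid,
  laid out ROI-major so that each ROI's six metrics form one group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .graphmetrics import GLOBAL_METRICS, NODAL_METRICS, subject_auc_features
from .network import SparsityGrid, compute_connectivity, edge_vector

__all__ = ["CohortFeatures", "cohort_features", "ConnectomeTransformer"]


@dataclass
class CohortFeatures:
    """Per-subject feature tables for one cohort."""

    edges: np.ndarray  # subjects x M
    global_auc: np.ndarray  # subjects x 7
    nodal_auc: np.ndarray  # subjects x (N*6), ROI-major
    subject_ids: list[str]
    n_roi: int

    def global_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.global_auc, index=self.subject_ids, columns=GLOBAL_METRICS)

    def nodal_frame(self) -> pd.DataFrame:
        cols = [f"roi{j:03d}_{m}" for j in range(self.n_roi) for m in NODAL_METRICS]
        return pd.DataFrame(self.nodal_auc, index=self.subject_ids, columns=cols)


def cohort_features(
    timeseries: dict[str, np.ndarray],
    grid: SparsityGrid | None = None,
    n_random: int = 100,
    seed: int = 0,
) -> CohortFeatures:
    """Connectivity + graph-metric AUC features for every subject.

    The null-model seed is offset per subject so ensembles are independent
    yet reproducible from the single base seed.
    """
    grid = grid or SparsityGrid()
    ids = list(timeseries)
    edges, gl, nod = [], [], []
    n_roi = None
    for k, sid in enumerate(ids):
        conn = compute_connectivity(timeseries[sid])
        n_roi = conn.shape[0]
        edges.append(edge_vector(conn))
        g, nmat = subject_auc_features(conn, grid, n_random=n_random, seed=seed + 100_000 * k)
        gl.append(g)
        nod.append(nmat.reshape(-1))
    return CohortFeatures(
        edges=np.array(edges),
        global_auc=np.array(gl),
        nodal_auc=np.array(nod),
        subject_ids=ids,
        n_roi=int(n_roi),
    )


class ConnectomeTransformer(BaseEstimator, TransformerMixin):
    """Stateless sklearn transformer: list of T x N time-series matrices in,
    concatenated [edges | global AUC | nodal AUC] feature matrix out.

    Fitted attributes expose the column blocks (``edge_slice_``,
    ``global_slice_``, ``nodal_slice_``) for downstream modality-aware
    estimators such as :class:`connectomeclf.mksvm.MultiKernelSVC`.
    """

    def __init__(self, grid: SparsityGrid | None = None, n_random: int = 100, seed: int = 0):
        self.grid = grid
        self.n_random = n_random
        self.seed = seed

    def fit(self, X, y=None):
        first = np.asarray(X[0])
        n_roi = first.shape[1]
        m = n_roi * (n_roi - 1) // 2
        self.n_roi_ = n_roi
        self.edge_slice_ = slice(0, m)
        self.global_slice_ = slice(m, m + len(GLOBAL_METRICS))
        self.nodal_slice_ = slice(m + len(GLOBAL_METRICS), m + len(GLOBAL_METRICS) + n_roi * len(NODAL_METRICS))
        return self

    def transform(self, X):
        if not hasattr(self, "n_roi_"):
            self.fit(X)
        feats = cohort_features(
            {f"s{i}": np.asarray(x) for i, x in enumerate(X)},
            grid=self.grid,
            n_random=self.n_random,
            seed=self.seed,
        )
        return np.hstack([feats.edges, feats.global_auc, feats.nodal_auc])
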