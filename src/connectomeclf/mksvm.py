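"""Multi-kernel SVM: convex combination of per-modality Gram matrices.

Each feature modality m (connections, global graph metrics, nodal graph
metrics) is standardized on the training subjects, mapped to a linear Gram
matrix k_m, trace-normalized, and combined as K = sum_m beta_m k_m with
beta on the probability simplex.  The combined kernel feeds a soft-margin
SVM dual (box constraint 0 <= alpha_i <= C, sum alpha_i y_i = 0, solved by
libsvm through scikit-learn); beta and C are chosen by grid search inside
the cross-validation scheme, never on held-out subjects.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "build_kernel",
    "combine_kernels",
    "simplex_grid",
    "MultiKernelSVC",
    "Standardizer",
]


class Standardizer:
    """Per-column z-scoring with training-row statistics; zero-variance
    columns are dropped with a warning."""

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        self.std_ = X.std(axis=0, ddof=0)
        self.keep_ = self.std_ > 0
        if not self.keep_.all():
            warnings.warn(
                f"{int((~self.keep_).sum())} zero-variance feature(s) dropped",
                UserWarning,
            )
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Z = (X[:, self.keep_] - self.mean_[self.keep_]) / self.std_[self.keep_]
        return Z


def build_kernel(
    train_features: np.ndarray,
    test_features: np.ndarray | None = None,
    kernel: str = "linear",
    gamma: float | None = None,
):
    """Gram matrix for one modality, trace-normalized on the training block.

    Features must already be standardized with training statistics.  Returns
    K_train (n x n) or, when ``test_features`` is given, the pair
    (K_train, K_cross) where K_cross is test x train.
    """
    Xtr = np.asarray(train_features, dtype=float)
    n = Xtr.shape[0]
    if kernel == "linear":
        k_tr = Xtr @ Xtr.T
    elif kernel == "rbf":
        g = gamma if gamma is not None else 1.0 / max(Xtr.shape[1], 1)
        sq = (Xtr**2).sum(1)
        k_tr = np.exp(-g * (sq[:, None] + sq[None, :] - 2 * Xtr @ Xtr.T))
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    tr = np.trace(k_tr)
    scale = n / tr if tr > 0 else 1.0
    k_tr = scale * (k_tr + k_tr.T) / 2.0
    if test_features is None:
        return k_tr
    Xte = np.asarray(test_features, dtype=float)
    if kernel == "linear":
        k_cross = Xte @ Xtr.T
    else:
        g = gamma if gamma is not None else 1.0 / max(Xtr.shape[1], 1)
        d = (Xte**2).sum(1)[:, None] + (Xtr**2).sum(1)[None, :] - 2 * Xte @ Xtr.T
        k_cross = np.exp(-g * d)
    return k_tr, scale * k_cross


def combine_kernels(kernels, beta) -> np.ndarray:
    """Weighted sum sum_m beta_m K_m with simplex weights."""
    beta = np.asarray(beta, dtype=float)
    if len(kernels) != beta.size:
        raise ValueError("one weight per kernel required")
    if np.any(beta < -1e-12) or abs(beta.sum() - 1.0) > 1e-9:
        raise ValueError("kernel weights must be nonnegative and sum to 1")
    shapes = {k.shape for k in kernels}
    if len(shapes) != 1:
        raise ValueError(f"kernel dimension mismatch: {shapes}")
    out = np.zeros_like(kernels[0], dtype=float)
    for b, k in zip(beta, kernels):
        out += b * k
    return out


def simplex_grid(n_modalities: int, step: float = 0.1) -> np.ndarray:
    """All weight vectors on the probability simplex with resolution ``step``.

    For 3 modalities at step 0.1 this enumerates the 66 compositions of 10
    into 3 nonnegative parts.
    """
    denom = int(round(1.0 / step))
    if abs(denom * step - 1.0) > 1e-9:
        raise ValueError("step must divide 1 evenly")
    pts = [
        np.array(c, dtype=float) / denom
        for c in itertools.product(range(denom + 1), repeat=n_modalities)
        if sum(c) == denom
    ]
    return np.array(pts)


class MultiKernelSVC(BaseEstimator, ClassifierMixin):
    """SVM on a fixed convex combination of per-modality kernels.

    Parameters
    ----------
    C : float
        Soft-margin box constraint.
    beta : array-like or None
        Simplex weights over modalities (None: uniform).
    modality_slices : list of slice or None
        Column blocks of the concatenated feature matrix belonging to each
        modality; None treats the whole matrix as a single modality.
    kernel : {"linear", "rbf"}
    standardize : bool
        Z-score each modality on the training rows before the kernel.

    Attributes (after fit)
    ----------------------
    alpha_ : (n,) dual coefficients in [0, C] (zeros off the support).
    dual_signed_ : (n,) y_i * alpha_i, summing to ~0.
    intercept_, support_, beta_, classes_
    """

    def __init__(
        self,
        C: float = 1.0,
        beta=None,
        modality_slices=None,
        kernel: str = "linear",
        gamma: float | None = None,
        standardize: bool = True,
    ):
        self.C = C
        self.beta = beta
        self.modality_slices = modality_slices
        self.kernel = kernel
        self.gamma = gamma
        self.standardize = standardize

    def _slices(self, n_cols: int):
        return self.modality_slices or [slice(0, n_cols)]

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("training labels must contain both classes")
        if self.C <= 0:
            raise ValueError("C must be positive")
        slices = self._slices(X.shape[1])
        beta = (
            np.full(len(slices), 1.0 / len(slices))
            if self.beta is None
            else np.asarray(self.beta, dtype=float)
        )
        self.scalers_ = []
        self.X_blocks_ = []
        kernels = []
        for sl in slices:
            block = X[:, sl]
            if self.standardize:
                sc = Standardizer().fit(block)
                block = sc.transform(block)
            else:
                sc = None
            self.scalers_.append(sc)
            self.X_blocks_.append(block)
            kernels.append(build_kernel(block, kernel=self.kernel, gamma=self.gamma))
        self.kernels_ = kernels
        self.beta_ = beta
        K = combine_kernels(kernels, beta)
        self._svc = SVC(C=self.C, kernel="precomputed")
        self._svc.fit(K, y)
        n = X.shape[0]
        self.support_ = self._svc.support_.copy()
        self.dual_signed_ = np.zeros(n)
        self.dual_signed_[self.support_] = self._svc.dual_coef_[0]
        self.alpha_ = np.abs(self.dual_signed_)
        self.intercept_ = float(self._svc.intercept_[0])
        return self

    def _cross_kernel(self, X):
        X = np.asarray(X, dtype=float)
        slices = self._slices(X.shape[1])
        crosses = []
        for sl, sc, tr_block in zip(slices, self.scalers_, self.X_blocks_):
            block = X[:, sl]
            if sc is not None:
                block = sc.transform(block)
            _, k_cross = build_kernel(tr_block, block, kernel=self.kernel, gamma=self.gamma)
            crosses.append(k_cross)
        return combine_kernels(crosses, self.beta_)

    def decision_function(self, X):
        check_is_fitted(self, "alpha_")
        return self._svc.decision_function(self._cross_kernel(X))

    def predict(self, X):
        check_is_fitted(self, "alpha_")
        return self._svc.predict(self._cross_kernel(X))
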