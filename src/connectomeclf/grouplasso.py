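"""Group-LASSO logistic regression with an exact block soft-threshold prox.

Minimizes

    sum_i log(1 + exp(-y_i (x_i . w + c)))  +  lam * sum_j ||w_j||_2

where columns are partitioned into groups j (here: the six nodal graph
metrics of one ROI form one group), the intercept c is unpenalized and the
group penalty is the Euclidean norm of each block, so a group is either
exactly zero or jointly active.  Solved by monotone FISTA (accelerated
proximal gradient with a fallback plain step whenever the accelerated step
would increase the objective), step size by backtracking line search.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["GroupLassoLogistic", "lambda_max", "group_soft_threshold", "tune_lambda"]


def _logistic_loss_grad(w, c, X, y):
    z = y * (X @ w + c)
    # stable log(1 + exp(-z))
    loss = float(np.logaddexp(0.0, -z).sum())
    s = -y * _sigmoid(-z)  # d loss / d margin-term
    grad_w = X.T @ s
    grad_c = float(s.sum())
    return loss, grad_w, grad_c


def _sigmoid(t):
    out = np.empty_like(t)
    pos = t >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-t[pos]))
    et = np.exp(t[~pos])
    out[~pos] = et / (1.0 + et)
    return out


def group_soft_threshold(w: np.ndarray, thresh: float, group_ids: np.ndarray) -> np.ndarray:
    """Blockwise shrinkage: w_j <- max(0, 1 - thresh/||w_j||) * w_j."""
    out = w.copy()
    for g in np.unique(group_ids):
        sel = group_ids == g
        norm = np.linalg.norm(w[sel])
        if norm <= thresh:
            out[sel] = 0.0
        else:
            out[sel] *= 1.0 - thresh / norm
    return out


def _group_penalty(w, group_ids):
    return float(
        sum(np.linalg.norm(w[group_ids == g]) for g in np.unique(group_ids))
    )


def lambda_max(X: np.ndarray, y: np.ndarray, group_ids: np.ndarray) -> float:
    """Smallest penalty at which the all-zero weight vector is optimal.

    With w = 0 the optimal unpenalized intercept is log(n+/n-); the zero
    solution satisfies the stationarity condition iff every group's gradient
    block norm is <= lam, so lam_max is the largest block norm at that point.
    """
    n_pos = int((y > 0).sum())
    n_neg = int((y < 0).sum())
    c0 = np.log(n_pos / n_neg)
    _, grad_w, _ = _logistic_loss_grad(np.zeros(X.shape[1]), c0, X, y)
    return max(
        float(np.linalg.norm(grad_w[group_ids == g])) for g in np.unique(group_ids)
    )


def tune_lambda(
    X: np.ndarray,
    y: np.ndarray,
    group_ids: np.ndarray,
    fracs=(0.7, 0.5, 0.35, 0.25, 0.15, 0.1),
    cv: int = 3,
    seed: int = 0,
) -> float:
    """Pick the penalty from a grid of fractions of lambda_max by cross-
    validated accuracy with the one-standard-error rule: among penalties
    whose CV accuracy is within one SE of the best, take the largest
    (sparsest) one.  Optional — the pipeline default keeps lam fixed at 1.
    """
    from sklearn.model_selection import StratifiedKFold

    lm = lambda_max(X, y, group_ids)
    grid = sorted((f * lm for f in fracs), reverse=True)
    results = []
    folds = list(StratifiedKFold(cv, shuffle=True, random_state=seed).split(X, y))
    for lam in grid:
        accs = []
        for tr, te in folds:
            m = GroupLassoLogistic(groups=group_ids, lam=lam, max_iter=2000, tol=1e-7)
            m.fit(X[tr], y[tr])
            accs.append(float((m.predict(X[te]) == np.asarray(y)[te]).mean()))
        results.append((lam, float(np.mean(accs)), float(np.std(accs) / np.sqrt(cv))))
    best_acc = max(r[1] for r in results)
    best_se = next(r[2] for r in results if r[1] == best_acc)
    for lam, acc, _ in results:  # grid is descending: first hit is the sparsest
        if acc >= best_acc - best_se:
            return lam
    return results[-1][0]


class GroupLassoLogistic(BaseEstimator, ClassifierMixin):
    """Sparse logistic regression with a per-group L2 penalty.

    Parameters
    ----------
    groups : array-like of shape (n_features,), optional
        Group label per column.  Default: every column its own group
        (ordinary LASSO-like behavior with per-coordinate soft threshold).
    lam : float, default 1.0
        Penalty strength; 0 gives the unregularized maximum-likelihood fit.
    max_iter, tol :
        FISTA iteration cap and relative-objective convergence tolerance.

    Attributes
    ----------
    coef_ : (n_features,) weight vector (zero groups are exactly zero).
    intercept_ : float
    group_norms_ : dict group label -> ||w_j||_2
    n_iter_, converged_, objective_, objective_path_
    """

    def __init__(self, groups=None, lam: float = 1.0, max_iter: int = 10000, tol: float = 1e-8):
        self.groups = groups
        self.lam = lam
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite feature values")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("GroupLassoLogistic is a binary classifier")
        ypm = np.where(y == self.classes_[1], 1.0, -1.0)
        n, p = X.shape
        gid = (
            np.arange(p)
            if self.groups is None
            else np.asarray(self.groups)
        )
        if gid.shape[0] != p:
            raise ValueError("groups must have one label per feature column")

        w = np.zeros(p)
        c = float(np.log((ypm > 0).sum() / (ypm < 0).sum()))
        # Lipschitz bound of the logistic gradient: ||[X, 1]||^2 / 4
        aug_norm = np.linalg.norm(np.hstack([X, np.ones((n, 1))]), 2)
        step = 4.0 / (aug_norm**2 + 1e-12)

        def objective(wv, cv):
            z = ypm * (X @ wv + cv)
            return float(np.logaddexp(0.0, -z).sum()) + self.lam * _group_penalty(wv, gid)

        obj = objective(w, c)
        path = [obj]
        vw, vc = w.copy(), c  # momentum point
        t_k = 1.0
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            loss_v, gw, gc = _logistic_loss_grad(vw, vc, X, ypm)
            # backtracking from the Lipschitz-bound step
            st = step
            while True:
                w_new = group_soft_threshold(vw - st * gw, st * self.lam, gid)
                c_new = vc - st * gc
                z = ypm * (X @ w_new + c_new)
                loss_new = float(np.logaddexp(0.0, -z).sum())
                dw = np.concatenate([w_new - vw, [c_new - vc]])
                quad = loss_v + gw @ (w_new - vw) + gc * (c_new - vc) + (dw @ dw) / (2 * st)
                if loss_new <= quad + 1e-12:
                    break
                st /= 2.0
            obj_new = loss_new + self.lam * _group_penalty(w_new, gid)
            if obj_new > obj:  # monotone fallback: plain proximal step from (w, c)
                loss_w, gw, gc = _logistic_loss_grad(w, c, X, ypm)
                st = step
                while True:
                    w_new = group_soft_threshold(w - st * gw, st * self.lam, gid)
                    c_new = c - st * gc
                    z = ypm * (X @ w_new + c_new)
                    loss_new = float(np.logaddexp(0.0, -z).sum())
                    dw = np.concatenate([w_new - w, [c_new - c]])
                    quad = loss_w + gw @ (w_new - w) + gc * (c_new - c) + (dw @ dw) / (2 * st)
                    if loss_new <= quad + 1e-12:
                        break
                    st /= 2.0
                obj_new = loss_new + self.lam * _group_penalty(w_new, gid)
                t_k = 1.0  # restart momentum
            t_next = (1.0 + np.sqrt(1.0 + 4.0 * t_k**2)) / 2.0
            vw = w_new + ((t_k - 1.0) / t_next) * (w_new - w)
            vc = c_new + ((t_k - 1.0) / t_next) * (c_new - c)
            t_k = t_next
            rel = abs(obj - obj_new) / max(abs(obj), 1.0)
            w, c, obj = w_new, c_new, min(obj_new, obj)
            path.append(obj)
            if rel < self.tol:
                converged = True
                break
        if not converged:
            warnings.warn("group-LASSO solver hit max_iter before convergence", UserWarning)
        self.coef_ = w
        self.intercept_ = float(c)
        self.group_ids_ = gid
        self.group_norms_ = {
            g: float(np.linalg.norm(w[gid == g])) for g in np.unique(gid)
        }
        self.n_iter_ = it
        self.converged_ = converged
        self.objective_ = obj
        self.objective_path_ = np.asarray(path)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_

    def predict(self, X):
        d = self.decision_function(X)
        return np.where(d >= 0, self.classes_[1], self.classes_[0])

    def predict_proba(self, X):
        p1 = _sigmoid(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def kkt_violation(self, X, y) -> float:
        """Max over zero groups of (gradient block norm - lam); <= 0 at an
        exact optimum, small positive at numerical convergence."""
        check_is_fitted(self, "coef_")
        ypm = np.where(np.asarray(y) == self.classes_[1], 1.0, -1.0)
        _, gw, _ = _logistic_loss_grad(self.coef_, self.intercept_, np.asarray(X, float), ypm)
        worst = -np.inf
        for g, norm in self.group_norms_.items():
            if norm == 0.0:
                worst = max(worst, float(np.linalg.norm(gw[self.group_ids_ == g])) - self.lam)
        return worst
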