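"""Nested leave-one-out evaluation and end-to-end pipeline orchestration.

The evaluation scheme: each subject is held out once (outer LOOCV); on the
remaining subjects the edge screen, the group-LASSO nodal selection and all
standardization statistics are recomputed, and an inner LOOCV grid search
over C in {2^-5 .. 2^5} and simplex kernel weights beta picks the
hyperparameters before the outer model is refit and applied to the held-out
subject.  Nothing computed from a held-out subject ever enters its own
training fold.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .evaluate import confusion_counts, delong_test, mann_whitney_auc, performance_metrics
from .features import CohortFeatures, cohort_features
from .grouplasso import GroupLassoLogistic
from .mksvm import MultiKernelSVC, Standardizer, build_kernel, combine_kernels, simplex_grid
from .network import SparsityGrid
from .selection import consensus_edges, edge_ttest_select, nodal_group_ids

__all__ = [
    "RunConfig",
    "ClassificationResult",
    "nested_loocv",
    "compare_global_metrics",
    "compare_nodal_metrics",
    "run_pipeline",
    "MODALITY_COMBOS",
]

MODALITY_COMBOS = ["C", "G", "N", "C+G", "C+N", "G+N", "C+G+N"]


@dataclass
class RunConfig:
    """Reproducible configuration for a full pipeline run."""

    manifest: str = ""
    out_dir: str = "results"
    s_min: float = 0.02
    s_max: float = 0.5
    s_step: float = 0.01
    alpha: float = 0.05
    lam: float = 1.0
    c_exponents: tuple[int, ...] = tuple(range(-5, 6))
    beta_step: float = 0.1
    n_random: int = 100
    seed: int = 0
    positive_class: int = 1
    fisher_edges: bool = False
    combos: tuple[str, ...] = tuple(MODALITY_COMBOS)

    @property
    def grid(self) -> SparsityGrid:
        return SparsityGrid(self.s_min, self.s_max, self.s_step)

    @property
    def c_grid(self) -> np.ndarray:
        return 2.0 ** np.asarray(self.c_exponents, dtype=float)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["c_exponents"] = list(self.c_exponents)
        d["combos"] = list(self.combos)
        return d

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        for key in ("c_exponents", "combos"):
            if key in known and isinstance(known[key], list):
                known[key] = tuple(known[key])
        return cls(**known)


@dataclass
class ClassificationResult:
    """Pooled outer-fold predictions and derived performance."""

    modalities: tuple[str, ...]
    y_true: np.ndarray
    y_pred: np.ndarray
    decision_values: np.ndarray
    fold_params: list[dict]
    tp: int
    fn: int
    tn: int
    fp: int
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    consensus_edges: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def to_dict(self) -> dict:
        return {
            "modalities": list(self.modalities),
            "y_true": self.y_true.tolist(),
            "y_pred": self.y_pred.tolist(),
            "decision_values": self.decision_values.tolist(),
            "fold_params": self.fold_params,
            "confusion": {"TP": self.tp, "FN": self.fn, "TN": self.tn, "FP": self.fp},
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "n_consensus_edges": int(self.consensus_edges.size),
            "consensus_edges": self.consensus_edges.tolist(),
        }


def _parse_combo(combo) -> tuple[str, ...]:
    if isinstance(combo, str):
        return tuple(part for part in combo.split("+") if part)
    return tuple(combo)


try:  # low-level libsvm entry point: ~7x less per-call overhead than SVC in
    # the hyperparameter grid search; predictions verified against SVC in tests
    from sklearn.svm import _libsvm as _fast_libsvm

    _fast_libsvm.set_verbosity_wrap(0)
except ImportError:  # pragma: no cover
    _fast_libsvm = None


def _loo_predict(K: np.ndarray, y01: np.ndarray, C: float, j: int, tr: np.ndarray) -> float:
    if _fast_libsvm is not None:
        Kf = np.ascontiguousarray(K[np.ix_(tr, tr)])
        model = _fast_libsvm.fit(Kf, y01[tr], svm_type=0, kernel="precomputed", C=C)
        Kt = np.ascontiguousarray(K[j, tr][None, :])
        return float(
            _fast_libsvm.predict(Kt, *model[:7], svm_type=0, kernel="precomputed")[0]
        )
    from sklearn.svm import SVC  # pragma: no cover

    svc = SVC(C=C, kernel="precomputed").fit(K[np.ix_(tr, tr)], y01[tr])
    return float(svc.predict(K[j, tr][None, :])[0])


def _inner_loocv_accuracy(K: np.ndarray, y: np.ndarray, C: float) -> float:
    n = len(y)
    y01 = np.ascontiguousarray((np.asarray(y) == np.unique(y)[1]).astype(np.float64))
    K = np.ascontiguousarray(K, dtype=np.float64)
    correct = 0
    for j in range(n):
        tr = np.delete(np.arange(n), j)
        if y01[tr].min() == y01[tr].max():
            continue  # degenerate inner fold: count as error
        pred = _loo_predict(K, y01, C, j, tr)
        correct += int((pred > 0.5) == (y01[j] > 0.5))
    return correct / n


def _select_modalities(
    feats: CohortFeatures,
    y: np.ndarray,
    train_idx: np.ndarray,
    modalities: tuple[str, ...],
    alpha: float,
    lam: float,
    fisher: bool,
):
    """Per-fold feature selection on training rows; returns the modality
    feature matrices (full cohort rows, selected columns) plus bookkeeping."""
    blocks: dict[str, np.ndarray] = {}
    info: dict[str, object] = {}
    if "C" in modalities:
        sel = edge_ttest_select(feats.edges, y, train_idx, alpha=alpha, fisher=fisher)
        chosen = sel.selected
        if chosen.size == 0:
            warnings.warn("no edge passed the t-test screen; using the smallest-p edge", UserWarning)
            chosen = np.array([int(np.argmin(sel.p))])
        blocks["C"] = feats.edges[:, chosen]
        info["edge_selection"] = chosen
    if "G" in modalities:
        blocks["G"] = feats.global_auc
    if "N" in modalities:
        gid = nodal_group_ids(feats.n_roi)
        sc = Standardizer().fit(feats.nodal_auc[train_idx])
        Xz = sc.transform(feats.nodal_auc[train_idx])
        gl = GroupLassoLogistic(groups=gid[sc.keep_], lam=lam, max_iter=3000, tol=1e-7)
        gl.fit(Xz, y[train_idx])
        cols_kept = np.flatnonzero(sc.keep_)
        nz = cols_kept[gl.coef_ != 0.0]
        if nz.size == 0:
            warnings.warn("group-LASSO zeroed every nodal feature; using all columns", UserWarning)
            nz = np.arange(feats.nodal_auc.shape[1])
        blocks["N"] = feats.nodal_auc[:, nz]
        info["nodal_selection"] = nz
    return [blocks[m] for m in modalities], info


def nested_loocv(
    feats: CohortFeatures,
    y: np.ndarray,
    combo="C+G+N",
    config: RunConfig | None = None,
) -> ClassificationResult:
    """Outer LOOCV with per-fold selection and inner LOOCV hyperparameter search.

    Hyperparameter ties resolve deterministically: highest inner accuracy,
    then smaller C, then beta closest to uniform, then grid order.
    """
    config = config or RunConfig()
    modalities = _parse_combo(combo)
    y = np.asarray(y)
    n = len(y)
    if n < 6 or min((y == config.positive_class).sum(), (y != config.positive_class).sum()) < 3:
        raise ValueError("need >= 6 subjects and >= 3 per class")
    betas = simplex_grid(len(modalities), config.beta_step)
    c_grid = config.c_grid
    uniform = np.full(len(modalities), 1.0 / len(modalities))
    preds = np.empty(n, dtype=y.dtype)
    decisions = np.empty(n, dtype=float)
    fold_params: list[dict] = []
    edge_sets: list[np.ndarray] = []
    for held in range(n):
        train = np.delete(np.arange(n), held)
        try:
            mats, info = _select_modalities(
                feats, y, train, modalities, config.alpha, config.lam, config.fisher_edges
            )
        except Exception as exc:
            raise RuntimeError(f"feature selection failed in outer fold {held}: {exc}") from exc
        if "edge_selection" in info:
            edge_sets.append(info["edge_selection"])  # type: ignore[arg-type]
        # per-modality kernels on the outer-training rows
        kernels = []
        for mat in mats:
            sc = Standardizer().fit(mat[train])
            kernels.append(build_kernel(sc.transform(mat[train])))
        best = None  # (acc, C, dist_to_uniform, grid index, beta)
        for bi, beta in enumerate(betas):
            K = combine_kernels(kernels, beta)
            dist = float(np.linalg.norm(beta - uniform))
            for C in c_grid:
                acc = _inner_loocv_accuracy(K, y[train], C)
                key = (-acc, C, dist, bi)
                if best is None or key < best[0]:
                    best = (key, C, beta)
        _, C_star, beta_star = best
        model = MultiKernelSVC(
            C=C_star,
            beta=beta_star,
            modality_slices=_concat_slices(mats),
        )
        X_all = np.hstack(mats)
        model.fit(X_all[train], y[train])
        decisions[held] = float(model.decision_function(X_all[held][None, :])[0])
        preds[held] = model.predict(X_all[held][None, :])[0]
        fold_params.append(
            {
                "fold": held,
                "C": float(C_star),
                "beta": np.asarray(beta_star).tolist(),
                "n_edges": int(len(info.get("edge_selection", []))),
                "n_nodal": int(len(info.get("nodal_selection", []))),
            }
        )
    tp, fn, tn, fp = confusion_counts(y, preds, positive=config.positive_class)
    auc = mann_whitney_auc(decisions, y, positive=config.positive_class)
    perf = performance_metrics(tp, fn, tn, fp, auc)
    cons = consensus_edges(edge_sets) if edge_sets else np.array([], dtype=int)
    return ClassificationResult(
        modalities=modalities,
        y_true=y.copy(),
        y_pred=preds,
        decision_values=decisions,
        fold_params=fold_params,
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
        accuracy=perf.accuracy,
        sensitivity=perf.sensitivity,
        specificity=perf.specificity,
        auc=auc,
        consensus_edges=cons,
    )


def _concat_slices(mats) -> list[slice]:
    slices, start = [], 0
    for m in mats:
        slices.append(slice(start, start + m.shape[1]))
        start += m.shape[1]
    return slices


def compare_global_metrics(global_auc: pd.DataFrame, y, positive=1, q_thresh: float = 0.05) -> pd.DataFrame:
    """Two-sample pooled t per global metric with Benjamini–Hochberg FDR.

    Zero-variance metrics are excluded from the family with a warning.
    Direction is the sign of mean(positive) - mean(negative).
    """
    from .selection import _pooled_ttest

    y = np.asarray(y)
    X = global_auc.to_numpy(dtype=float)
    a, b = X[y == positive], X[y != positive]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 subjects per group")
    t, p = _pooled_ttest(a, b)
    ok = np.isfinite(t)
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} zero-variance metric(s) excluded from the FDR family",
            UserWarning,
        )
    q = np.full_like(p, np.nan)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "metric": list(global_auc.columns),
            "mean_pos": a.mean(axis=0),
            "mean_neg": b.mean(axis=0),
            "direction": np.sign(a.mean(axis=0) - b.mean(axis=0)),
            "t": t,
            "p": p,
            "q": q,
            "significant": q < q_thresh,
        }
    )


def compare_nodal_metrics(feats: CohortFeatures, y, positive=1, q_thresh: float = 0.05) -> dict[str, pd.DataFrame]:
    """Per-metric nodal comparisons, FDR-corrected across nodes within each metric."""
    from .graphmetrics import NODAL_METRICS

    out = {}
    nodal = feats.nodal_auc.reshape(len(feats.subject_ids), feats.n_roi, len(NODAL_METRICS))
    for k, metric in enumerate(NODAL_METRICS):
        df = compare_global_metrics(
            pd.DataFrame(nodal[:, :, k], columns=[f"roi{j:03d}" for j in range(feats.n_roi)]),
            y,
            positive=positive,
            q_thresh=q_thresh,
        )
        df = df.rename(columns={"metric": "node"})
        out[metric] = df
    return out


def _provenance_hash(manifest_path: Path, timeseries: dict[str, np.ndarray]) -> str:
    h = hashlib.sha256()
    h.update(Path(manifest_path).read_bytes())
    for sid in sorted(timeseries):
        h.update(sid.encode())
        h.update(np.ascontiguousarray(timeseries[sid]).tobytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline from a manifest and write all artifacts.

    Stages: load -> connectivity/graph features -> group comparisons ->
    nested LOOCV per modality combination -> DeLong table vs the full
    combination.  Every output embeds the configuration for provenance.
    """
    from .cohort import load_cohort

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str):
        log_lines.append(f"[{time.strftime('%Y-%m-%d %H:%M:%S')}] {msg}")

    log(f"config: {json.dumps(config.to_dict())}")
    t0 = time.time()
    try:
        manifest, series, roi_names = load_cohort(config.manifest)
    except Exception as exc:
        raise RuntimeError(f"stage=load: {exc}") from exc
    y = manifest["label"].to_numpy()
    log(f"stage=load n={len(y)} hash={_provenance_hash(Path(config.manifest), series)} "
        f"dt={time.time() - t0:.1f}s")

    t0 = time.time()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        feats = cohort_features(
            {sid: series[sid] for sid in manifest["subject_id"]},
            grid=config.grid,
            n_random=config.n_random,
            seed=config.seed,
        )
    for w in caught:
        log(f"warning: {w.message}")
    log(f"stage=features dt={time.time() - t0:.1f}s")
    feats.global_frame().to_csv(out_dir / "global_auc.csv")
    feats.nodal_frame().to_csv(out_dir / "nodal_auc.csv")

    t0 = time.time()
    comparison = compare_global_metrics(feats.global_frame(), y, positive=config.positive_class)
    comparison.to_csv(out_dir / "global_comparison.csv", index=False)
    log(f"stage=compare dt={time.time() - t0:.1f}s")

    results: dict[str, ClassificationResult] = {}
    for combo in config.combos:
        t0 = time.time()
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            results[combo] = nested_loocv(feats, y, combo=combo, config=config)
        for w in caught:
            log(f"warning[{combo}]: {w.message}")
        log(f"stage=classify[{combo}] acc={results[combo].accuracy:.3f} dt={time.time() - t0:.1f}s")

    full = config.combos[-1]
    delong_rows = []
    for combo in config.combos:
        if combo == full:
            continue
        cmp_res = delong_test(
            results[combo].decision_values,
            results[full].decision_values,
            y,
            positive=config.positive_class,
        )
        delong_rows.append(
            {
                "combo": combo,
                "vs": full,
                "auc": cmp_res.auc1,
                "auc_full": cmp_res.auc2,
                "z": cmp_res.z,
                "p": cmp_res.p,
            }
        )
    payload = {
        "config": config.to_dict(),
        "results": {k: v.to_dict() for k, v in results.items()},
        "delong": delong_rows,
    }
    (out_dir / "results.json").write_text(json.dumps(payload, indent=1))
    roc_rows = []
    for combo, res in results.items():
        order = np.argsort(-res.decision_values)
        pos = res.y_true == config.positive_class
        tpr = np.cumsum(pos[order]) / max(pos.sum(), 1)
        fpr = np.cumsum(~pos[order]) / max((~pos).sum(), 1)
        for f, t_ in zip(fpr, tpr):
            roc_rows.append({"combo": combo, "fpr": f, "tpr": t_})
    pd.DataFrame(roc_rows).to_csv(out_dir / "roc_points.csv", index=False)
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    return payload
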