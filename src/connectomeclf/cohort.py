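"""Synthetic two-group cohorts of ROI time series with planted network effects.

The generator emulates a resting-state fMRI case/control study at the scale of
~20 subjects per group, 90 atlas regions and ~230 retained volumes.  Each
subject's regional signal is drawn from a stationary multivariate Gaussian
whose correlation matrix carries a block "community" structure; the
patient-like group receives a planted coupling change on a designated edge set
(either a weight shift on specific edges, or a weakening of between-module
coupling that raises modularity and path length).  Because the downstream
connectivity statistic is the Pearson correlation, the covariance fully
determines the population network — richer temporal dynamics would add nothing
that the pipeline could measure.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as _signal

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "CohortData",
    "build_population_covariance",
    "simulate_subject",
    "generate_cohort",
    "between_module_pairs",
    "within_module_pairs",
    "default_cohort_spec",
]

POS_LABEL = 1
NEG_LABEL = -1


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a two-group synthetic cohort.

    Parameters
    ----------
    n_group_pos, n_group_neg:
        Subjects in the patient-like (+1) and control-like (-1) groups.
    n_roi:
        Number of regions (network nodes).
    n_timepoints:
        Retained volumes per subject.
    module_sizes:
        Community sizes; must sum to ``n_roi``.
    within_module_weight, between_module_weight:
        Base population correlation inside / between communities.
    effect_edges:
        Unordered ROI index pairs carrying the group effect.
    effect_delta:
        Signed correlation change added to each effect edge in the positive
        group (before positive-definiteness repair).
    noise_sd:
        Standard deviation of i.i.d. observation noise added on top of the
        unit-variance latent signal.
    ar_coef:
        Optional AR(1) temporal smoothing of the latent draws (0 disables);
        the stationary marginal covariance is preserved.
    seed:
        Base RNG seed; per-subject seeds are derived deterministically.
    """

    n_group_pos: int = 22
    n_group_neg: int = 20
    n_roi: int = 90
    n_timepoints: int = 230
    module_sizes: tuple[int, ...] = ()
    within_module_weight: float = 0.35
    between_module_weight: float = 0.08
    effect_edges: tuple[tuple[int, int], ...] = ()
    effect_delta: float = 0.0
    noise_sd: float = 0.6
    ar_coef: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_group_pos < 1 or self.n_group_neg < 1:
            raise ValueError("both groups need at least one subject")
        sizes = tuple(self.module_sizes) or _default_modules(self.n_roi)
        object.__setattr__(self, "module_sizes", sizes)
        if sum(sizes) != self.n_roi:
            raise ValueError(
                f"module_sizes {sizes} sum to {sum(sizes)}, expected n_roi={self.n_roi}"
            )
        edges = []
        for i, j in self.effect_edges:
            if i == j:
                raise ValueError(f"effect edge ({i},{j}) is a self-loop")
            if not (0 <= i < self.n_roi and 0 <= j < self.n_roi):
                raise ValueError(f"effect edge ({i},{j}) outside 0..{self.n_roi - 1}")
            edges.append((min(i, j), max(i, j)))
        if len(set(edges)) != len(edges):
            raise ValueError("duplicate effect edges")
        object.__setattr__(self, "effect_edges", tuple(edges))
        if self.n_timepoints < self.n_roi:
            warnings.warn(
                "n_timepoints < n_roi: per-subject correlation matrices will be "
                "rank deficient",
                UserWarning,
                stacklevel=2,
            )
        if not (0 <= self.ar_coef < 1):
            raise ValueError("ar_coef must lie in [0, 1)")

    @property
    def module_assignment(self) -> np.ndarray:
        return np.repeat(np.arange(len(self.module_sizes)), self.module_sizes)

    @property
    def n_subjects(self) -> int:
        return self.n_group_pos + self.n_group_neg


def _default_modules(n_roi: int) -> tuple[int, ...]:
    # six communities, mirroring the coarse subnetwork structure of a 90-region atlas
    n_mod = 6 if n_roi >= 12 else max(2, n_roi // 3)
    base = n_roi // n_mod
    sizes = [base] * n_mod
    for k in range(n_roi - base * n_mod):
        sizes[k] += 1
    return tuple(sizes)


@dataclass
class GroundTruth:
    """Planted population structure of a generated cohort."""

    cov_pos: np.ndarray
    cov_neg: np.ndarray
    differential_edges: tuple[tuple[int, int], ...]
    realized_deltas: tuple[float, ...]
    module_assignment: np.ndarray
    spec: CohortSpec

    def to_json(self) -> str:
        payload = {
            "differential_edges": [list(e) for e in self.differential_edges],
            "realized_deltas": list(self.realized_deltas),
            "module_assignment": self.module_assignment.tolist(),
            "spec": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(self.spec).items()
            },
        }
        return json.dumps(payload, indent=1)


def _repair_spd(c: np.ndarray) -> np.ndarray:
    """Shift the spectrum to enforce positive definiteness, then rescale to
    unit diagonal.  No-op for matrices that are already comfortably PD."""
    lam_min = float(np.linalg.eigvalsh(c)[0])
    if lam_min <= 1e-10:
        c = c + (abs(lam_min) + 1e-6) * np.eye(c.shape[0])
    d = np.sqrt(np.diag(c))
    c = c / np.outer(d, d)
    np.fill_diagonal(c, 1.0)
    return (c + c.T) / 2.0


def build_population_covariance(spec: CohortSpec, group: str) -> np.ndarray:
    """Population correlation matrix for ``group`` in {"pos", "neg"}.

    Block-constant community structure with the planted effect added on
    ``spec.effect_edges`` for the positive group, followed by a smallest-
    eigenvalue repair and re-scaling to unit diagonal.
    """
    if group not in ("pos", "neg"):
        raise ValueError("group must be 'pos' or 'neg'")
    labels = spec.module_assignment
    same = labels[:, None] == labels[None, :]
    c = np.where(same, spec.within_module_weight, spec.between_module_weight).astype(float)
    np.fill_diagonal(c, 1.0)
    if group == "pos":
        for i, j in spec.effect_edges:
            val = c[i, j] + spec.effect_delta
            if abs(val) >= 1.0:
                raise ValueError(
                    f"effect_delta={spec.effect_delta} drives edge ({i},{j}) to "
                    f"correlation {val:+.3f}, outside (-1, 1)"
                )
            c[i, j] = c[j, i] = val
    repaired = _repair_spd(c)
    if np.linalg.eigvalsh(repaired)[0] <= 0:
        raise ValueError("covariance could not be repaired to positive definite")
    return repaired


def simulate_subject(
    cov: np.ndarray,
    n_timepoints: int,
    noise_sd: float,
    seed: int,
    ar_coef: float = 0.0,
) -> np.ndarray:
    """Draw a T x N time-series matrix from N(0, cov) plus white noise.

    Rows are time points.  With ``ar_coef`` > 0 the latent innovations are
    AR(1)-smoothed with the stationary variance normalized back to one, so the
    marginal covariance is unchanged while spectra become band-limited.
    """
    cov = np.asarray(cov, dtype=float)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance must be symmetric positive definite") from exc
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_timepoints, cov.shape[0]))
    if ar_coef > 0:
        z = _signal.lfilter([np.sqrt(1 - ar_coef**2)], [1.0, -ar_coef], z, axis=0)
        z[0] /= np.sqrt(1 - ar_coef**2)  # keep the first row unit variance
    x = z @ chol.T
    if noise_sd > 0:
        x = x + noise_sd * rng.standard_normal(x.shape)
    return x


def _subject_seed(base_seed: int, index: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class CohortData:
    """In-memory generated cohort: manifest, time series and ground truth."""

    manifest: pd.DataFrame
    timeseries: dict[str, np.ndarray]
    ground_truth: GroundTruth
    roi_names: list[str] = field(default_factory=list)

    @property
    def labels(self) -> np.ndarray:
        return self.manifest["label"].to_numpy()

    def write(self, out_dir: str | Path) -> Path:
        """Write manifest CSV, per-subject TSV time series and ground-truth JSON."""
        out_dir = Path(out_dir)
        ts_dir = out_dir / "timeseries"
        ts_dir.mkdir(parents=True, exist_ok=True)
        manifest = self.manifest.copy()
        paths = []
        for sid in manifest["subject_id"]:
            path = ts_dir / f"{sid}.tsv"
            df = pd.DataFrame(self.timeseries[sid], columns=self.roi_names)
            df.to_csv(path, sep="\t", index=False)
            paths.append(str(path.relative_to(out_dir)))  # relocatable manifest
        manifest["path"] = paths
        manifest = manifest[["subject_id", "path", "label", "group_name"]]
        manifest.to_csv(out_dir / "manifest.csv", index=False)
        (out_dir / "ground_truth.json").write_text(self.ground_truth.to_json())
        return out_dir / "manifest.csv"


def generate_cohort(spec: CohortSpec) -> CohortData:
    """Generate the full cohort described by ``spec``.

    Subjects are labeled +1 (patient-like) / -1 (control-like); per-subject
    seeds derive deterministically from ``spec.seed`` and the subject index,
    so any subject can be regenerated in isolation.
    """
    cov_pos = build_population_covariance(spec, "pos")
    cov_neg = build_population_covariance(spec, "neg")
    diff = np.abs(cov_pos - cov_neg)
    np.fill_diagonal(diff, 0.0)
    ii, jj = np.where(np.triu(diff, 1) > 1e-9)
    differential = tuple((int(a), int(b)) for a, b in zip(ii, jj))
    deltas = tuple(float(cov_pos[a, b] - cov_neg[a, b]) for a, b in differential)
    gt = GroundTruth(
        cov_pos=cov_pos,
        cov_neg=cov_neg,
        differential_edges=differential,
        realized_deltas=deltas,
        module_assignment=spec.module_assignment,
        spec=spec,
    )
    roi_names = [f"ROI{k:03d}" for k in range(spec.n_roi)]
    rows, series = [], {}
    for idx in range(spec.n_subjects):
        pos = idx < spec.n_group_pos
        sid = f"sub-{idx:03d}"
        cov = cov_pos if pos else cov_neg
        series[sid] = simulate_subject(
            cov, spec.n_timepoints, spec.noise_sd, _subject_seed(spec.seed, idx), spec.ar_coef
        )
        rows.append(
            {
                "subject_id": sid,
                "path": "",
                "label": POS_LABEL if pos else NEG_LABEL,
                "group_name": "patient" if pos else "control",
            }
        )
    manifest = pd.DataFrame(rows)
    return CohortData(manifest=manifest, timeseries=series, ground_truth=gt, roi_names=roi_names)


def between_module_pairs(spec: CohortSpec) -> tuple[tuple[int, int], ...]:
    """All unordered ROI pairs whose endpoints lie in different communities."""
    labels = spec.module_assignment
    n = spec.n_roi
    return tuple(
        (i, j) for i in range(n) for j in range(i + 1, n) if labels[i] != labels[j]
    )


def within_module_pairs(spec: CohortSpec) -> tuple[tuple[int, int], ...]:
    labels = spec.module_assignment
    n = spec.n_roi
    return tuple(
        (i, j) for i in range(n) for j in range(i + 1, n) if labels[i] == labels[j]
    )


def sample_effect_edges(
    spec: CohortSpec,
    n_edges: int,
    seed: int,
    max_degree: int = 2,
    between_only: bool = True,
) -> tuple[tuple[int, int], ...]:
    """Random effect-edge set with bounded per-node planted degree.

    Capping how many planted edges touch any one node bounds the spectral
    norm of the planted perturbation (its smallest eigenvalue is at least
    -max_degree * |effect_delta|), which keeps the positive-group matrix
    positive definite without triggering the repair step — so the two
    population covariances differ exactly on the planted edges.
    """
    rng = np.random.default_rng(seed)
    candidates = list(between_module_pairs(spec) if between_only else
                      between_module_pairs(spec) + within_module_pairs(spec))
    for _ in range(200):  # greedy over a fresh shuffle until the budget fits
        order = rng.permutation(len(candidates))
        degree = np.zeros(spec.n_roi, dtype=int)
        chosen: list[tuple[int, int]] = []
        for k in order:
            i, j = candidates[k]
            if degree[i] < max_degree and degree[j] < max_degree:
                chosen.append((i, j))
                degree[i] += 1
                degree[j] += 1
            if len(chosen) == n_edges:
                return tuple(sorted(chosen))
    raise ValueError(
        f"cannot place {n_edges} edges with max planted degree {max_degree}"
    )


def default_cohort_spec(**overrides) -> CohortSpec:
    """Study-scale defaults: 22 patient-like vs 20 control-like subjects,
    90 regions, 230 time points."""
    params = dict(n_group_pos=22, n_group_neg=20, n_roi=90, n_timepoints=230)
    params.update(overrides)
    return CohortSpec(**params)


def load_cohort(manifest_path: str | Path) -> tuple[pd.DataFrame, dict[str, np.ndarray], list[str]]:
    """Read a manifest CSV and its referenced TSV time-series files."""
    manifest = pd.read_csv(manifest_path)
    required = {"subject_id", "path", "label"}
    if not required <= set(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    series: dict[str, np.ndarray] = {}
    roi_names: list[str] = []
    for _, row in manifest.iterrows():
        path = Path(row["path"])
        if not path.is_absolute():
            path = Path(manifest_path).parent / path
        try:
            df = pd.read_csv(path, sep="\t")
        except OSError as exc:
            raise OSError(f"cannot read time series for subject {row['subject_id']}: {exc}")
        series[row["subject_id"]] = df.to_numpy(dtype=float)
        roi_names = list(df.columns)
    return manifest, series, roi_names
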