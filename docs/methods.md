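# Methods

`connectomeclf` implements a complete two-group functional-connectome
classification analysis: from per-subject ROI time series to a multi-kernel
SVM decision per held-out subject, with every intermediate product (networks,
graph metrics, selected features) exposed. This note records the model, the
parameters that matter, the numerical choices, and what the synthetic
benchmark does and does not demonstrate.

## Network construction

Connectivity between two regions is the Pearson correlation of their time
series. Negative correlations are set to zero before anything else happens —
the analysis is restricted to positive coupling — and the diagonal is zero.
From the weighted matrix, binary undirected graphs are built at each sparsity
threshold `s` on the grid 0.02–0.50 in steps of 0.01 (49 thresholds by
default): the `k = round(s · N(N−1)/2)` strongest edges are kept. Rounding is
half-up, and ties at the cutoff weight break by lexicographic edge index, so
degenerate inputs binarize deterministically and edge sets are nested across
the grid. If fewer than `k` positive edges exist, all positive edges are kept
and a warning fires.

Optional per-column linear detrending and a 4th-order zero-phase Butterworth
band-pass (e.g. 0.01–0.1 Hz) are available for real BOLD inputs; both default
to off because the synthetic data need neither.

## Graph metrics

Per threshold: global clustering coefficient `C_p`, characteristic path
length `L_p`, global efficiency `E_global`, modularity `Q`, and the
null-model-normalized `γ = C_p/⟨C_p^rand⟩`, `λ = L_p/⟨L_p^rand⟩`,
`σ = γ/λ`; per node: betweenness (Brandes, unnormalized), degree, clustering,
efficiency, local efficiency and mean shortest path.

Low thresholds on sparse cohort networks are disconnected by construction, so
path-type metrics must not blow up: `L_p` and nodal shortest path average
over *reachable* pairs only (isolated nodes report 0), and efficiency-type
metrics use `1/∞ = 0`. This is the common connectome-toolbox convention and
keeps all 49 thresholds usable.

`Q` is maximized by agglomerative greedy merging: start from singletons and
repeatedly merge the community pair with the largest gain
`ΔQ = e_ij/L − d_i d_j / (2L²)`, stopping when no gain is positive; ties
break on the lowest merge-pair index. The reported `Q` is recomputed from the
final partition with `Q = Σ_i [l_i/L − (d_i/2L)²]`. Tests verify the greedy
value never exceeds the exhaustive-partition maximum on small graphs and
reaches ≥ 90 % of it on average.

The null model for `γ/λ/σ` is Maslov–Sneppen degree-preserving rewiring:
10·|E| attempted double-edge swaps per graph, 100 graphs per ensemble by
default, seeded. Ensembles are built per threshold. Rewiring is written
directly (rather than via `networkx.double_edge_swap`) because the ensemble
is defined by *attempted* swaps, which keeps cost predictable on very sparse
graphs.

The threshold-free feature of a metric is its plain sum over the grid
("AUC over sparsity"; no step-width weighting), giving 7 global features and
N×6 nodal features per subject. Hubs are the top `ceil(0.05·N)` nodes by
group-mean degree AUC, ties broken by index.

## Feature selection

*Connections.* Pooled-variance two-sample t-tests per edge on training
subjects only; edges with `p < 0.05` (uncorrected — this is a per-fold
screen, not an inference) enter the classifier. Edges selected in *every*
outer fold form the consensus set reported as the biomarker. Edges with zero
pooled variance are excluded with a warning. A Fisher r-to-z flag exists for
edge weights; default off.

*Nodal metrics.* Each ROI's six nodal AUCs form one group in a group-LASSO
logistic regression: logistic loss plus `λ_pen · Σ_j ‖w_j‖₂` with an
unpenalized intercept, so a region's metrics are selected or discarded
jointly. Features are z-scored on training rows first ("Fisher
Z-normalization" of metric features is read as standardization; the r-to-z
map applies to correlations, which these are not). The default penalty is
`λ_pen = 1`; an optional cross-validated grid (fractions of the analytic
`λ_max`, one-standard-error rule) is provided but off by default.

The solver is monotone FISTA: accelerated proximal gradient with the exact
block soft-threshold prox, backtracking line search from the Lipschitz bound
`‖[X,1]‖²/4`, and a fallback plain proximal step (with momentum restart)
whenever an accelerated step would increase the objective — this guarantees
a non-increasing objective path and exactly-zero groups. Convergence:
relative objective change < 1e−8 or 10 000 iterations. At `λ_pen = 0` the
solution matches an unregularized maximum-likelihood fit to 1e−4 per
coefficient; at `λ_pen ≥ λ_max` all weights are exactly zero and the
intercept is `log(n₊/n₋)`.

## Classification

Three modalities — selected edge weights (C), the 7 global AUCs (G), the
group-LASSO-selected nodal AUCs (N) — are each z-scored on training rows,
mapped to a linear Gram matrix and trace-normalized to `trace(K) = n`. The
combined kernel is `K = Σ_m β_m K_m` with `β` on the probability simplex.
The kernel form is linear (minimal choice consistent with small n; RBF
available behind a flag), and the decision threshold is fixed at 0.

The SVM dual (box constraint `0 ≤ α_i ≤ C`, `Σ α_i y_i = 0`) is solved by
libsvm via scikit-learn on the precomputed combined kernel; dual
coefficients, support set and the constraint residuals are exposed on the
fitted estimator and audited in tests. At a simplex vertex the multi-kernel
decision values reproduce a single-kernel SVM to 1e−6.

**Nested LOOCV.** Each subject is held out once. On the remaining n−1
subjects the edge screen, the group-LASSO selection and all standardization
statistics are recomputed; an inner LOOCV grid search over
`C ∈ {2⁻⁵,…,2⁵}` × simplex-grid `β` (step 0.1 → 66 points for three
modalities) picks the hyperparameters by inner accuracy, with deterministic
tie-breaks (smaller C, then β closest to uniform, then grid order); the
model is refit on all n−1 subjects and applied to the held-out one. Pooled
held-out predictions give the confusion counts, accuracy/sensitivity/
specificity, and a Mann–Whitney AUC over decision values (ties ½). The
positive class is the patient-like group and is configurable.

Correlated AUCs of different modality combinations on the same subjects are
compared with DeLong's placement-value covariance estimator (two-sided
normal p; identical score vectors return z = 0, p = 1 by convention).
Group differences in the global metric AUCs use pooled t-tests with
Benjamini–Hochberg correction across the 7-metric family (nodal comparisons
are corrected within each metric across nodes).

## Synthetic cohorts

Subjects are i.i.d. draws from a stationary multivariate Gaussian whose
correlation matrix has block-community structure (`within_module_weight`
inside blocks, `between_module_weight` outside, unit diagonal), plus white
observation noise of standard deviation `noise_sd` (an optional AR(1) flag
adds band-limited temporal smoothing with the marginal covariance
preserved). Because downstream connectivity is the Pearson correlation, the
covariance fully determines the population network; richer hemodynamics
would add nothing the pipeline could measure. Defaults mirror the emulated
study scale: 22 patient-like + 20 control-like subjects, 90 ROIs in six
communities, 230 time points, `within = 0.35`, `between = 0.08`,
`noise_sd = 0.6` (so observed correlations are population values shrunk by
`1/(1+noise_sd²) ≈ 0.74`, giving realistic single-subject edge noise of
about 0.06 at T = 230).

The patient-like group's matrix adds `effect_delta` to each designated
effect edge. Two planting styles are used: (a) edge effects on a sparse set
of between-module pairs, with at most two planted edges per node — this
bounds the perturbation's smallest eigenvalue by `−2|δ|` and keeps the
matrix positive definite, so the two population covariances differ *exactly*
on the planted edges; (b) topology effects that weaken *all* between-module
couplings, raising modularity and weakening global integration in the
patient-like group. If a requested configuration is indefinite anyway, a
smallest-eigenvalue shift plus re-scaling to unit diagonal repairs it; the
repair slightly shrinks and smears planted deltas, so the ground-truth
object stores post-repair values, and recovery experiments use the
bounded-degree planting that avoids repair. Per-subject seeds derive from
`(cohort seed, subject index)`, making any subject reproducible in
isolation.

**What the benchmark does not show.** The generator has no hemodynamic
response, motion, physiological confounds, site effects or heavy-tailed
noise; real fMRI effect sizes are smaller and spatially diffuse. Passing
tests demonstrate that the pipeline is leakage-free, calibrated under the
null, and recovers planted effects of realistic magnitude — not that any
particular clinical accuracy is attainable.

## Problem sizes in tests and the acceptance script

Recovery and calibration experiments run at reduced ROI counts (12–24) and
coarsened grids (e.g. 0.1–0.5 step 0.05), chosen so each check completes in
minutes while keeping the tested property far from its pass boundary. One
size choice is substantive, not computational: at 90 ROIs the edge screen's
calibrated 5 % false-positive rate yields ~200 false edges against 20
planted ones, so no screen at α = 0.05 can reach Jaccard ≥ 0.6 there —
planted-set recovery is therefore evaluated at ~20 ROIs, where the
false-positive budget (~10 edges) makes the target meaningful. The
permutation-null check keeps the full 42-subject design with a
vertices-only β grid.

## Known limitations

- The greedy modularity optimizer is the plain agglomerative ΔQ variant;
  "modified" greedy implementations in some toolboxes may partition
  differently on the same graph (Q values agree to within the greedy gap).
- Whether normalized small-world indices should use one null ensemble per
  subject or per threshold is a convention choice; per-threshold is used.
- With all-equal edge weights the sparsity thresholding is deterministic but
  arbitrary (lexicographic); weighted-network analysis is out of scope.
- LOOCV accuracy estimates at n = 42 have high variance; single-permutation
  accuracies far from 50 % are expected and only the permutation mean is
  calibrated.
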