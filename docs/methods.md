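# Methods

This note documents the models implemented in `nbstrat`, the defaults and the
reasoning behind the open design choices.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself compute.

## Multi-view kernel k-means

Given views `X^(1..V)` on one sample set, each view contributes a bank of RBF
Gram matrices `K(x,y) = exp(-γ‖x-y‖²)` over the bandwidth grid
γ ∈ {2⁻¹⁴ … 2⁻¹⁹}.  That grid is matched to log2-scale expression matrices
with thousands of genes, where squared sample-to-sample distances run from
the thousands to the hundreds of thousands, so the grid spans kernels from
locally discriminating to nearly linear.  The composite kernel is
`K̃ = Σ_v w_v^p K^(v)` with simplex weights and sparsity exponent p.

The objective is the composite within-cluster distortion
`Σ_v w_v^p D_v` with

    D_v = Σ_c [ Σ_{i∈c} K^(v)_ii − (1/|c|) Σ_{i,j∈c} K^(v)_ij ],

the within-cluster scatter of view v's feature space.  The fit alternates:

1. kernel k-means assignment sweeps on K̃ until the labels stabilize — each
   sample moves to the cluster minimizing
   `K_ii − (2/|c|)Σ_{j∈c}K_ij + (1/|c|²)Σ_{j,l∈c}K_jl` with centroids frozen
   from the previous labels, ties to the lowest cluster index;
2. the weight update `w_v ∝ D_v^(-1/(p-1))`, the KKT minimizer of the
   objective over the simplex at fixed labels (verified in the tests against
   exhaustive simplex grid search).

Both steps are descent steps, so the objective trace is non-increasing; the
tests assert this over seeded random problems, and that with a single linear
kernel the procedure reproduces classical Lloyd k-means exactly.

Numerical/degenerate choices:

* **p = 1 is rejected** — the weight minimizer degenerates to winner-take-all
  on the single smallest-distortion kernel; the useful grid is {1.5, 2, 2.5},
  with 1.5 the default.  Large p flattens weights toward uniform.
* **Zero-distortion kernels** receive all weight, split uniformly among them
  (the limit of the closed form).
* **Empty clusters** are repaired deterministically by moving the sample
  farthest from its current centroid (in the composite feature space) into
  the empty cluster.
* **Initialization** is uniform weights plus seeded uniform-random labels;
  convergence requires stable labels *and* relative objective change below
  `tol` (default 1e-8); default 30 restarts, lowest final objective wins.
* Per-kernel weights are learned individually and summed within views for
  reporting, so a view's weight is the sum over its six bandwidths.

## Cluster-count and sparsity selection

Validity indices are computed on the feature-space metric induced by the
final composite kernel, `d(i,j) = √(K̃_ii + K̃_jj − 2K̃_ij)` — the space the
clustering actually optimizes; the metric is config-visible because other
choices are defensible.  Three indices are used: mean silhouette
`(b_i−a_i)/max(a_i,b_i)` (singletons score 0; maximize), the Dunn index
(minimum between-cluster distance over maximum within-cluster diameter;
maximize; defined as +inf when all clusters are points), and connectivity
with neighborhood size L = 10 (each of a sample's L nearest neighbors in a
foreign cluster adds `1/j` for neighbor rank j; minimize; L = 10 is the
common default of its source literature).

Per restart, one fit per candidate k is scored, the three per-index rankings
are aggregated by weighted Spearman-footrule distance, and the top candidate
recorded; the final k is the mode over restarts, ties broken toward the
smaller k (parsimony).  The aggregation weights default to equal across the
three indices and are config-exposed.  The aggregation is solved by exact
enumeration over permutations (candidate lists here have ≤ 5 entries, so the
stochastic search the aggregation literature uses for large candidate sets
would find the identical optimum less reproducibly); lists beyond 8
candidates are rejected.  The sparsity exponent is selected from its grid by
mean silhouette at fixed k, ties toward the smaller p.

## Survival evaluation

**Cox with Firth's correction.**  With >80 % right censoring, discovered
two-group stratifications regularly produce monotone partial likelihoods
(all early events in one arm), where the unpenalized Cox estimate diverges.
The Firth/Jeffreys penalty fixes this: the fit maximizes
`l*(β) = l(β) + ½ log det I(β)` with `l` the Breslow partial log-likelihood
(Breslow tie handling: simplest consistent choice) and `I` its observed
information.  The implementation maximizes `l*` numerically (BFGS with
numeric gradients) rather than via the modified-score Newton iteration of the
classical implementations — the designs in scope have ≤ 5 covariates, and the
tests verify the optimum against direct grid search.  Standard errors come
from `I(β̂)⁻¹`; Wald p-values and 95 % CIs `exp(β ± 1.96·se)` follow.  Wald
CIs are a deliberate simplification: the classical Firth-Cox software
defaults to profile-penalized-likelihood CIs, so CI endpoints (not point
estimates) may differ from that software in small samples.  BIC is
`−2·loglik + m·ln(n)` evaluated at the *penalized* optimum, a choice flagged
here because the two log-likelihoods differ by O(log det I).

**AFT with censoring imputation.**  Ordinary least squares of log-time on
the covariates, iterated with truncated-normal mean imputation: censored
log-times start at their log censoring times; each round refits OLS, then
replaces each censored response with `μ_i + σ·φ(z_i)/(1−Φ(z_i))`,
`z_i = (log c_i − μ_i)/σ` — the conditional mean of the fitted normal above
the known censoring bound (so imputed times never fall below censoring
times).  Iteration stops at max-change < 1e-6 or 50 rounds; a collapsed
residual scale aborts the fit.

**Metrics.**  The censoring-adjusted rmse works on the log scale (survival
times span orders of magnitude): events contribute `(log T − log T̂)²`,
censored rows only `max(0, log c − log T̂)²`, penalizing predictions below
the known survival lower bound and nothing else.  Harrell's c counts pairs
comparable when the earlier observed time is an event, concordant when the
shorter-lived patient has the higher risk score, ties half; the AFT risk
score is the negative predicted log-time.  Cross-validation is 10-fold × 10
repeats, folds stratified by the event indicator — without stratification,
80 % censoring routinely produces event-free folds; a fold draw whose
training folds have fewer than two events is redrawn (up to 10 times).

**Stratification comparison.**  Each candidate enters the Cox and AFT models
as reference-coded cluster indicators alongside age and ordinal stage
(integer-coded).  The reported HR/CI/p belong to the first cluster indicator;
for k > 2 the remaining indicators stay in the model and in the fit object.
The literature high-risk/low-risk labels are evaluated identically as the
baseline row.  Constant assignments are skipped with a warning.

## Supervised endpoint prediction

Feature ranking is one-way ANOVA F per gene; the top 1000 are selected
*inside each training split*, never from test data.  The classifier is a
linear max-margin model (delegated to a standard solver; the protocol —
selection, tuning, evaluation — is the bespoke surface).  The cost grid
defaults to {1e-6, 1e-5, 1e-4, 1e-3, 0.1, 0.5, 1, 2, 5, 10, 20, 50, 100,
1000}: the published form of this grid is typeset with positive exponents,
which yields a non-monotone sequence, so the negative-exponent reading is the
default and the literal reading remains selectable.  (C, class-weight mode)
are chosen by 5-fold inner CV accuracy, ties toward smaller C and uniform
weights; "balanced" multiplies each class's C inversely to its frequency.
Evaluation is AUROC (rank-based, ties half) and balanced accuracy at the
zero decision threshold.  Cross-cohort runs first restrict both cohorts to
their exactly-matching gene identifiers (no alias resolution), then apply the
clinical context filter (all / high-risk only / MYCN-non-amplified only,
missing MYCN excluded) identically to both sides.

## Synthetic cohorts

The generator emulates the structural features the pipeline depends on:

* **Views.**  Each view has per-gene baselines ~N(7, 1) on the log2 scale.
  Informative views add cluster-specific mean offsets ~N(0, effect²) on their
  informative genes, with the residual noise shrunk so the total per-gene
  variance stays at noise_sd² — expression views live on a common scale, and
  subtype structure displaces means rather than inflating overall spread.
  (This matters: without it, a pure-noise view and an informative view have
  identical within-cluster distortions and kernel weighting cannot separate
  them.)  Offsets and baselines derive from a `signature_seed` separate from
  the cohort seed, so independently seeded cohorts share one planted biology
  — the premise of cross-cohort transfer.  Cross-view correlation is induced
  only through the shared labels.
* **Survival.**  Exponential event times with cluster-specific hazards
  (simplest proportional-hazards family; the evaluation layer assumes only
  right censoring); one global exponential censoring rate, bisected so the
  expected censored fraction `mean_i c/(λ_i+c)` matches the target.
* **Endpoints and covariates.**  OS/EFS labels are the event indicator with
  symmetric flip noise, the EFS flip rate higher so EFS is the less
  unbalanced label; the high-risk flag is worst-cluster membership with 10 %
  flips; MYCN amplification is cluster-linked with 5 % missing; age is
  log-normal and stage ordinal 1–4, both weakly cluster-shifted.

Defaults are the study-like conditions: 498 patients, two subtypes at
(0.65, 0.35), three views ("rnaseq-mav", "rnaseq-rpm", "microarray") of 2000
genes with 10 % informative at effect 1.0 SD, hazards (1/3000, 5/3000) per
day, censoring target 0.80, flip rates OS 0.02 / EFS 0.12 / HR 0.10.  The
2000-gene views are this package's desk-scale stand-in for genome-wide
panels; the kernel bandwidth grid still operates in its intended distance
regime at that width.  The supervised transfer experiments instead use an
endpoint-dominant configuration (one 5000-gene view, 50 informative genes at
1.5 SD, hazards (3e-4, 0.2), censoring target 0.64) in which subtype
membership nearly determines the event indicator — emulating a cohort whose
endpoint has a strong expression signature, which is the regime the
cross-cohort protocol is designed for.

What the generator does **not** emulate: platform-specific count
distributions (negative-binomial RNA-seq counts), probe effects, batch
structure, aCGH segment structure, or residual cross-view correlation beyond
the shared labels.  Passing tests therefore demonstrate the correctness and
calibration of the algorithms under planted structure, not performance on
real cohorts.

## Problem sizes

The acceptance pipeline uses n = 498 with three 2000-gene views for the
unsupervised block and two n = 300 cohorts with 5000-gene views for the
supervised block; recovery and calibration tests use 100–400 samples.  These
sizes were chosen as the smallest at which the studied effects are stable
across seeds.

## Known limitations

* Wald (not profile-penalized) confidence intervals for the Firth-Cox fit.
* Gene matching across cohorts is exact-string; no symbol-alias resolution.
* The rank-aggregation candidate set is capped at 8 (exact enumeration).
* Kernel banks are dense; no low-rank approximation, so memory is O(m·n²).
* The AFT imputation assumes normal log-time residuals; heavy-tailed
  residual distributions will bias the truncated-mean imputation.
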