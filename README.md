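# nbstrat

Multi-view kernel k-means patient stratification with survival-based
evaluation, built for multi-platform gene-expression cohorts of the kind
collected for neuroblastoma outcome studies.

## The problem

Neuroblastoma outcomes range from spontaneous regression to relentless
progression, and the literature risk groups (high risk / low risk, driven by
MYCN amplification, age and stage) leave substantial prognostic variability
unexplained.  When the same patients are profiled on several platforms —
RNA-seq quantified two ways, microarray, optionally aCGH copy number — the
platforms carry complementary signal, and an integrative clustering can
recover subtypes that stratify survival better than the literature labels.

`nbstrat` implements that analysis end to end as a tested, reusable library:

1. **Multi-view kernel k-means (MVKKM).**  Each view is expanded into a bank
   of RBF kernels `K(x,y) = exp(-γ‖x-y‖²)` over the bandwidth grid
   γ ∈ {2⁻¹⁴, …, 2⁻¹⁹}, and the bank is combined into a composite kernel

       K̃ = Σ_v w_v^p K^(v),   w on the simplex, p > 1.

   The fit alternates kernel k-means assignment on K̃ with the closed-form
   re-weighting `w_v ∝ D_v^(-1/(p-1))`, where `D_v` is the within-cluster
   distortion of kernel *v* — the exact minimizer of the composite distortion
   `Σ_v w_v^p D_v` at fixed labels.  Restarts from seeded random partitions
   guard against local optima.
2. **Model selection.**  The cluster count is chosen by ranking candidate k
   by mean silhouette, Dunn index and connectivity on the composite-kernel
   distances and aggregating the three rankings with weighted Spearman-footrule
   rank aggregation; the sparsity exponent p is chosen from {1.5, 2, 2.5} by
   mean silhouette.
3. **Survival evaluation.**  Candidate stratifications are scored by
   Kaplan–Meier curves and the log-rank test, a Firth-penalized Cox
   proportional-hazards model (finite estimates under the separation that
   >80 % right censoring produces) with Wald tests and
   BIC = −2·loglik + m·ln(n), and an accelerated failure time model with
   iterative truncated-normal imputation of censored times, cross-validated
   (10×10, event-stratified) under a censoring-adjusted rmse and Harrell's
   c-index.
4. **Supervised endpoint prediction.**  ANOVA-F gene ranking, top-1000
   selection inside every training fold, a linear max-margin classifier tuned
   over a C grid with optional class-balanced weights by nested
   cross-validation, and cross-cohort evaluation (All→All, HR→HR,
   MYCN_NA→MYCN_NA contexts) by AUROC and balanced accuracy.
5. **Synthetic cohorts.**  A generator plants subtype structure across
   correlated views, cluster-linked exponential survival under calibrated
   heavy censoring, unbalanced OS/EFS labels, and risk covariates — so every
   stage of the pipeline is testable without any external download.

## Worked example

```python
import numpy as np
from sklearn.metrics import adjusted_rand_score
import nbstrat as nb

views = [nb.ViewSpec(n, n_genes=2000, n_informative=200, effect_size=1.0)
         for n in ("rnaseq-mav", "rnaseq-rpm", "microarray")]
cfg = nb.SyntheticConfig(n_samples=200, views=views, seed=0)
data, truth = nb.simulate_cohort(cfg)

bank = nb.build_kernel_bank(data, nb.DEFAULT_GAMMAS)
fit = nb.mvkkm_fit(bank, nb.MVKKMConfig(k=2, p=1.5, n_restarts=30, seed=0))
print("ARI vs planted subtypes:", round(adjusted_rand_score(truth.labels, fit.labels), 3))
print("learned view weights:", {v: round(w, 3) for v, w in fit.view_weights.items()})

surv = nb.SurvivalData(data.clinical.data["os_time"].to_numpy(float),
                       data.clinical.data["os_event"].to_numpy(int))
chi2, p, _ = nb.logrank_test(surv, fit.labels)
print(f"log-rank: chi2={chi2:.1f}, p={p:.2e}")

rows = nb.compare_stratifications([("MVKKM clusters", fit.labels)],
                                  data.clinical, surv, seed=0)
from nbstrat.survival import evaluations_to_frame
print(evaluations_to_frame(rows).to_string(index=False))
```

Output:

```
ARI vs planted subtypes: 1.0
learned view weights: {'rnaseq-mav': 0.335, 'rnaseq-rpm': 0.333, 'microarray': 0.332}
log-rank: chi2=20.8, p=5.15e-06
                Data  k HR (confidence interval)  Wald-test p-value        BIC     rmse  c-index
      MVKKM clusters  2         0.18 (0.07-0.45)           0.000273 275.047122 0.673553 0.681920
High Risk / Low Risk  2         3.62 (1.53-8.52)           0.003325 279.630182 0.684399 0.695644
```

The clustering recovers the planted two-subtype structure exactly (ARI 1.0);
the learned weights split nearly evenly across the three equally informative
views and sum to 1; the two clusters separate survival strongly (log-rank
p ≈ 5e-6); and the Cox model built on the discovered clusters fits better
(lower BIC, 275 vs 280) than the model built on the noisy risk-group labels.
The hazard ratio 0.18 says cluster-1 membership multiplies the hazard by 0.18
relative to cluster 0 (cluster orientation is arbitrary — its reciprocal,
5.5, is the same stratification described from the other side).

A command-line interface mirrors the main steps:

```sh
nbstrat simulate --config cohort.yaml --seed 1 --out cohort/
nbstrat select-k --view cohort/rnaseq-mav.tsv --k-min 2 --k-max 5 --seed 1
nbstrat evaluate --clusters clusters.csv --clinical cohort/clinical.csv
nbstrat predict-endpoint --train-view a.tsv --train-clinical a.csv \
    --test-view b.tsv --test-clinical b.csv --endpoint os --context hr
```

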