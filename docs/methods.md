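# Methods

`tmescore` implements a tumor-microenvironment (TME) scoring workflow for
bulk expression cohorts — the kind of analysis used to stratify luminal B
breast cancer patients by the immune composition of their tumors.  This
note records the models, the numerical choices, and what the synthetic
benchmark does and does not demonstrate.

## Workflow overview

1. **Deconvolution** (`deconvolution`): per-sample immune-cell scores from
   bulk expression by ν-support-vector regression against a genes ×
   cell-types reference signature (an LM22-like matrix, user-supplied or
   synthetic).
2. **TME subtyping** (`subtyping`): univariate prognostic screen of the
   cell scores, then resampling-based consensus clustering of the selected
   scores into subtypes TMEC1..k, with k chosen from the consensus-CDF
   delta-area curve.
3. **Phenotype genes** (`phenotype_genes`): negative-binomial Wald
   differential expression between subtypes, intersection of consistently
   up-regulated genes, removal of genes zero in ≥ 50% of samples, and
   KL-divergence NMF reclustering of samples on the retained genes.
4. **Signature construction** (`signature`): univariate Cox screen of the
   phenotype genes (p < 0.05), random-forest importance ranking with an
   mtry scan, selection of the > 95% cumulative-importance prefix, K-means
   grouping of the candidates into groups G1..Gk, and per-group PC1
   signature scores
   S_j(s) = Σ_i Pc1_i · Exp_i(s),
   with unit-norm loadings Pc1 and centered expression Exp.
5. **TME score** (`scoring`): multivariate Cox coefficients α over the
   group scores; TME score(s) = Σ_g α_g · PC1_g(s); median split into
   risk-h / risk-l.
6. **Evaluation and association** (`survival`, `genomic`): Kaplan-Meier /
   log-rank comparison of the risk groups, Harrell C-index, IPCW
   time-dependent AUC, immune-panel expression comparisons, and per-gene
   Fisher tests of mutation frequency after removing Silent/Intron records.

## Model assumptions

* Expression is linear-scale and nonnegative; mixtures are linear in cell
  fractions.  A heuristic (matrix maximum < 50) warns when input looks
  log-transformed.
* Survival follows proportional hazards; all Cox fits use the partial
  likelihood with Efron tie handling by default (clinical follow-up is
  day-granular and heavily tied; Breslow is available).
* Fractions are reported relative (row-normalized to 1); downstream use is
  rank- and comparison-based, so the normalization does not affect
  subtyping or scoring decisions.

## Key parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `nu_grid` | {0.25, 0.5, 0.75} | ν-SVR grid; min-RMSE ν kept |
| `n_permutations` | 1000 | gene-permutation null for per-sample significance |
| `cell_screen_p` | 0.05 | median-split log-rank threshold for prognostic cells |
| `consensus_k_min..k_max` | 2..10 | candidate cluster numbers |
| `consensus_reps` | 1000 | resampling repetitions (80% subsampling) |
| `delta_area_threshold` | 0.1 | elbow rule on relative CDF-area increments |
| `de_fdr` | 0.05 | BH threshold for DEGs; fold change unrestricted |
| `max_zero_fraction` | 0.5 | strict bound on per-gene zero fraction |
| `nmf_runs` / rank range / min membership | 50 / 2..10 / 10 | Brunet NMF consensus settings |
| `gene_cox_p` | 0.05 | univariate gene screen |
| `rf_mtry` / `rf_ntree_search` / `rf_ntree_final` | 1–235 / 500 / 100 | forest scan and final fit |
| `cumulative_importance` | 0.95 | candidate-gene prefix |
| `kmeans_k` | 3 | signature groups G1..G3 |
| `min_followup_days` | 30 | inclusive follow-up filter (exactly 30 days kept) |

All randomness flows from one root seed, split deterministically per stage
via `numpy.random.SeedSequence`.

## Design choices where the design was open

* **Deconvolution recipe.** The published CIBERSORT recipe is adopted:
  global z-standardization of the signature, z-scoring of the mixture,
  linear-kernel ν-SVR per ν, reconstruction without intercept,
  negative-coefficient clipping, sum-to-one normalization.  The
  permutation null permutes the mixture's gene labels; p uses the add-one
  estimator, so p ≥ 1/(n_perm+1).
* **k selection.** "Delta area and CDF" is operationalized as: area A(k)
  under the consensus CDF; delta(k) = (A(k)−A(k−1))/A(k−1) with
  delta(k_min) = A(k_min); chosen k = largest k with delta above a
  configurable threshold (0.1).  The full delta curve is always emitted.
* **DE test.** A simplified NB-Wald test: median-of-ratios size factors,
  pooled method-of-moments dispersion floored at 1e-8, delta-method SE on
  the log fold change, and a t reference with n_a+n_b−2 df (measured null
  rejection 0.045 at nominal 0.05 on a Poisson null with 40 vs 40
  samples).  This deliberately omits empirical-Bayes dispersion shrinkage;
  the selection criterion downstream is only "FDR < 0.05".
* **DE comparison design.** Subtypes are compared pairwise against the
  best-prognosis subtype (lowest event rate), and the up-regulated
  significant sets are intersected; the Venn partition is reported.
* **RF target.** The forest predicts the binary survival status
  (dead/alive) by default; the TME subtype label is available via
  `rf_target="tmec"`.  Importance is mean impurity decrease.
* **PC1 sign and scale.** Loadings are the unit-norm leading eigenvector of
  the genes-as-variables covariance; the sign is fixed so the loading
  vector correlates positively with the group's mean expression profile
  (ties toward a positive first coordinate).  Exp_i enters centered, which
  makes S_j a genuine PC projection; single-gene groups score as the
  centered gene with a warning.
* **Median-split ties** go to risk-l, so risk-h is strictly above the
  median.  The TME score is reported unscaled.
* **Time-dependent AUC** is the IPCW cumulative/dynamic estimator with
  reverse-KM censoring weights (1/G(t−) for cases); "5-year" means 1825
  days.  It matches scikit-survival's estimator to machine precision on
  shared inputs.
* **Mutation tests** are two-sided Fisher exact on binary mutated/wild
  status per gene after case-insensitive removal of Silent/Intron
  records; multiplicity of records per sample-gene is ignored.
* **Panel comparisons** default to nonparametric tests (Mann-Whitney U for
  two groups, Kruskal-Wallis for more) with BH adjustment across the
  panel, for determinism.

## Numerical choices

* Cox: Newton-Raphson with step-halving; convergence when the max step is
  below 1e-9 or 50 iterations; rank-deficient covariates and monotone
  likelihoods (diverging or non-finite coefficients) raise errors rather
  than returning silent output.
* ν-SVR solver tolerance is 1e-5 by default.  libsvm's optimizer becomes
  pathologically slow below that on noisy mixture targets, and at 1e-5 the
  pure-mixture fraction error is ~1e-5 — far below the noise floor of any
  realistic cohort.  Desk-scale pipeline runs use 1e-4 (recovery
  correlations are identical to 4 decimals).
* KL-NMF multiplicative updates assert a non-increasing objective at every
  iteration (tolerance 1e-8 relative); runs stop at relative objective
  change < 1e-6 or 500 iterations.
* K-means gene grouping: k-means++ with 10 restarts, best inertia kept;
  an empty cluster triggers reseeded restarts (max 50).
* BH adjustment passes NaN (untested genes) through.

## The synthetic benchmark

`synthetic.generate_cohort` draws: per-subtype Dirichlet cell fractions
(each subtype enriches a disjoint block of cell types, concentration 10 vs
2); expression = signature × fractions with multiplicative log-normal
noise (sd 0.1 by default — multiplicative noise preserves the
nonnegativity that deconvolution and NMF require); subtype marker genes
shifted by 1.5 log2 units after mixing (so DE positives have known
identity); exponential survival with log hazard linear in the fractions
(baseline 1/1500 events/day, administrative censoring at 10 years plus
independent exponential censoring, mean 2500 days — about 35% censoring);
and MAF-style mutation records with group-dependent Bernoulli rates,
including Silent/Intron records to exercise the filter.

The standard benchmark (`benchmark` module) uses 300 samples, 22 cell
types with 15 marker genes each, three subtypes, and planted log-hazard
coefficients +6 on three cell types and −4 on two — hazard ratios of
roughly 1.3–1.8 across the interquartile fraction range, a realistic
prognostic effect.

What passing tests on this benchmark show: each stage recovers structure
it is designed to detect, the test statistics are calibrated under their
nulls, and the algebraic stages are exact.  What they do not show:
performance on real cohorts with transcriptome-wide covariance, batch and
platform effects, reference-signature mismatch, or non-proportional
hazards — none of which the generator emulates.

## Problem sizes used in tests and the reproduction script

Simulation-based checks run at desk scale as the package's own choice of
problem size: consensus clustering at 200 resampling repetitions (the
method's behavior is stable well below the 1000-rep default), end-to-end
pipeline replicates at 150–200 samples with 8 marker genes per cell type,
permutation-calibration checks with a 5-type signature and a single-ν
grid (the add-one permutation p is calibrated for any statistic), and
forest scans over a reduced mtry grid.  Defaults are never changed by the
tests; scaled settings are passed explicitly.

## Known limitations

* The DE test is not DESeq2; on real count data its dispersion handling is
  cruder and its p-values differ.  It also accepts continuous nonnegative
  intensities, where the NB model is only an approximation.
* Absolute-mode deconvolution, batch correction, and reference-signature
  construction are out of scope; the signature matrix is an input.
* The multivariate Cox α are fit on the same cohort that is subsequently
  median-split, so the in-cohort hazard ratio of risk-h vs risk-l is
  optimistic; external validation logistics are out of scope.
* Consensus clustering subsamples samples only (no gene resampling), and
  alternative k-selection criteria (PAC, silhouette) are not implemented.
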