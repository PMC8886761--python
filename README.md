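# tmescore

Tumor-microenvironment (TME) scoring for bulk expression cohorts, built for
prognostic stratification of luminal B breast cancer and similar settings:
from immune-cell deconvolution of bulk expression, through consensus TME
subtyping and phenotype-gene selection, to a Cox-weighted gene-signature
score that splits a cohort into high- and low-risk groups, with survival
and genomic association analyses on top.

## The method

1. **Immune-cell scores.** Each bulk sample is deconvolved against a
   genes × cell-types reference signature (an LM22-like matrix) with
   linear-kernel ν-support-vector regression over ν ∈ {0.25, 0.5, 0.75};
   negative coefficients are clipped and the rest normalized to
   proportions.  Per-sample significance comes from a 1000-permutation
   gene-label null.
2. **TME subtypes.** Cell scores with prognostic association (median-split
   log-rank p < 0.05) are clustered by resampling-based consensus
   clustering (k ∈ [2, 10], 1000 repetitions, 80% subsampling); k is
   chosen at the elbow of the consensus-CDF delta-area curve.
3. **Phenotype genes.** Negative-binomial Wald differential expression
   between subtypes (BH FDR < 0.05, fold change unrestricted), intersected
   across comparisons, filtered of genes zero in ≥ 50% of samples, and
   optionally reclustered by KL-divergence ("brunet") NMF.
4. **Gene signature and TME score.** Surviving genes pass a univariate Cox
   screen (p < 0.05) and random-forest importance selection (> 95%
   cumulative importance); K-means groups the candidates into signatures
   G1..Gk.  Each group scores samples by its first principal component,

       S_j = Σ_i Pc1_i · Exp_i ,

   and a multivariate Cox fit over the group scores gives coefficients α:

       TME score = Σ_j α_j · PC1_j .

   Samples above the cohort median score are risk-h, the rest risk-l.
5. **Downstream.** Kaplan-Meier / log-rank comparison of the risk groups,
   Harrell C-index and IPCW time-dependent AUC, immune-panel expression
   comparisons (activation / checkpoint / TGF-β-EMT panels), and per-gene
   Fisher tests of mutation frequency after removing Silent/Intron
   records from MAF-style input.

Because the analysis needs cohorts with known ground truth, the package
ships a synthetic-cohort generator (`tmescore.synthetic`) that plants cell
fractions, subtypes, marker-gene shifts, fraction-linked exponential
survival, and group-linked mutations.  See `docs/methods.md` for models,
assumptions, and design decisions.

## Worked example

Simulate a cohort with three planted hazardous cell types and run the full
workflow:

```sh
tmescore simulate --n-samples 200 --seed 7 --out cohort/
tmescore run-all --expression cohort/expression.tsv \
    --clinical cohort/clinical.tsv \
    --signature cohort/signature_matrix.tsv \
    --maf cohort/mutations.tsv --seed 7 --out results/
```

The same analysis from Python:

```python
from tmescore.benchmark import benchmark_cohort, desk_pipeline_config
from tmescore.pipeline import run_pipeline

cohort, signature = benchmark_cohort(n_samples=200, seed=1,
                                     n_marker_genes_per_type=8)
res = run_pipeline(cohort.expression, cohort.clinical, signature,
                   desk_pipeline_config(seed=1), mutations=cohort.mutations)
print(res.evaluation)
```

which prints (run with seed 1):

```
{'logrank_chi2': 40.894244157341724, 'logrank_p': 1.6069371977782236e-10,
 'risk_h_vs_l_hr': 3.1313859922829406, 'c_index': 0.7046511627906977,
 'median_tme_score': -0.4057545131591578,
 'auc_3y': 0.7409695039495825, 'auc_5y': 0.7168668540514164}
```

Reading: the fitted TME score splits the synthetic cohort at its median
into a high-risk group dying about 3× faster than the low-risk group
(hazard ratio 3.13, log-rank p ≈ 2×10⁻¹⁰) — the pipeline has recovered
the planted association between cell-type composition and survival.  The
C-index (0.70) and 5-year AUC (0.72) quantify how well the continuous
score orders individual survival times.

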