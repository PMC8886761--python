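"""Synthetic cohort generator for the TME-scoring workflow.

Emulates the statistical structure the analysis assumes, so every stage can
be exercised without downloading a real cohort:

* bulk expression formed as signature-matrix x cell-fraction mixtures with
  multiplicative log-normal noise (keeps values nonnegative, as deconvolution
  and NMF require);
* planted sample subtypes with subtype-specific Dirichlet cell-fraction
  distributions and marker-gene log2 fold-change shifts applied after mixing
  (so the differential-expression stage has positives of known identity);
* exponential survival whose log hazard is linear in the cell fractions,
  with independent censoring — the proportional-hazards data-generating
  process every Cox fit downstream assumes;
* MAF-style mutation records with group-dependent Bernoulli rates, including
  Silent/Intron records so the mutation filter is exercised literally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .deconvolution import SignatureMatrix
from .io import ExpressionMatrix
from .survival import SurvivalData

# default per-gene-per-group mutation rates emulating a cohort where a few
# genes (TP53-like) differ in frequency between planted groups
_DEFAULT_MUTATION_RATES = {
    "MUT_TP53": (0.45, 0.15, 0.15),
    "MUT_PIK3CA": (0.30, 0.30, 0.30),
    "MUT_GATA3": (0.10, 0.10, 0.35),
    "MUT_MAP3K1": (0.08, 0.08, 0.08),
}

_SILENT_FRACTION = 0.25  # fraction of mutation records emitted as Silent/Intron


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults give the standard benchmark.

    The standard benchmark is 300 samples, 22 cell types with 15 markers
    each, 3 planted subtypes, log-normal noise sd 0.1 and a planted 1.5
    log2 fold change — a cohort on which every downstream stage has known
    ground truth.
    """

    n_samples: int = 300
    n_cell_types: int = 22
    n_marker_genes_per_type: int = 15
    n_background_genes: int = 100
    planted_k: int = 3
    dirichlet_concentration: np.ndarray | None = None  # (planted_k, n_cell_types)
    noise_sd: float = 0.1
    de_log2fc: float = 1.5
    n_de_genes_per_subtype: int = 20
    survival_betas: np.ndarray | None = None  # per-cell-type log-hazard coefficients
    baseline_hazard: float = 1.0 / 1500.0  # events per day
    censoring_time: float = 3650.0  # administrative horizon, days
    censor_mean: float = 2500.0  # mean of independent exponential censoring
    mutation_rates: dict | None = None  # None -> defaults resized to planted_k
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_cell_types", "n_marker_genes_per_type",
                     "planted_k"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_background_genes < 0:
            raise ValueError("n_background_genes must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.censoring_time > 0:
            raise ValueError("censoring_time must be > 0")
        if self.dirichlet_concentration is not None:
            conc = np.asarray(self.dirichlet_concentration, dtype=float)
            if conc.shape != (self.planted_k, self.n_cell_types):
                raise ValueError("dirichlet_concentration must be (planted_k, n_cell_types)")
            if (conc <= 0).any():
                raise ValueError("dirichlet concentrations must be strictly positive")
            self.dirichlet_concentration = conc
        if self.survival_betas is not None:
            self.survival_betas = np.asarray(self.survival_betas, dtype=float)
            if self.survival_betas.shape != (self.n_cell_types,):
                raise ValueError("survival_betas must have one entry per cell type")


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    true_fractions: pd.DataFrame  # samples x cell types
    true_subtype: pd.Series  # per-sample planted label
    clinical: SurvivalData
    mutations: pd.DataFrame  # MAF-subset columns
    truth: dict  # planted parameters, JSON-serializable

    def __post_init__(self) -> None:
        assert np.allclose(self.true_fractions.sum(axis=1), 1.0, atol=1e-9)
        assert (self.clinical.time > 0).all()
        mut_samples = set(self.mutations["Tumor_Sample_Barcode"])
        assert mut_samples <= set(self.clinical.sample_ids)


def generate_signature_matrix(n_marker_genes_per_type: int, n_cell_types: int,
                              seed: int) -> SignatureMatrix:
    """Block-structured cell-type reference matrix.

    Each cell type owns a disjoint set of marker genes expressed at least
    5-fold higher in that type than in any other; a shared low background
    keeps the matrix strictly positive.  Deterministic given the seed.
    """
    if n_marker_genes_per_type < 1 or n_cell_types < 1:
        raise ValueError("marker-gene and cell-type counts must be >= 1")
    rng = np.random.default_rng(seed)
    n_genes = n_marker_genes_per_type * n_cell_types
    # background in [1, 10); marker expression in [100, 500): ratio >= 10 > 5
    base = rng.uniform(1.0, 10.0, size=(n_genes, n_cell_types))
    for ct in range(n_cell_types):
        rows = slice(ct * n_marker_genes_per_type, (ct + 1) * n_marker_genes_per_type)
        base[rows, ct] = rng.uniform(100.0, 500.0, size=n_marker_genes_per_type)
    genes = [f"MK{ct:02d}_{g:03d}"
             for ct in range(n_cell_types) for g in range(n_marker_genes_per_type)]
    cols = [f"CT{ct:02d}" for ct in range(n_cell_types)]
    return SignatureMatrix(pd.DataFrame(base, index=genes, columns=cols))


def _default_concentrations(k: int, n_types: int, rng: np.random.Generator) -> np.ndarray:
    """Subtype-specific Dirichlet concentrations: each subtype enriches a
    disjoint handful of cell types over a flat base."""
    conc = np.full((k, n_types), 2.0)
    per = max(1, n_types // k)
    for j in range(k):
        enriched = np.arange(j * per, min((j + 1) * per, n_types))
        conc[j, enriched] = 10.0
    return conc


def generate_cohort(config: SimulationConfig, signature: SignatureMatrix) -> SyntheticCohort:
    """Draw a full synthetic cohort from the planted generative model."""
    if signature.n_cell_types != config.n_cell_types:
        raise ValueError(
            f"signature has {signature.n_cell_types} cell types, "
            f"config expects {config.n_cell_types}")
    rng = np.random.default_rng(config.seed)
    n, k = config.n_samples, config.planted_k
    samples = [f"S{i:04d}" for i in range(n)]
    cell_types = list(signature.cell_types)

    conc = (config.dirichlet_concentration
            if config.dirichlet_concentration is not None
            else _default_concentrations(k, config.n_cell_types, rng))
    subtype = rng.integers(0, k, size=n)
    fractions = np.vstack([rng.dirichlet(conc[s]) for s in subtype])

    sig = signature.data.to_numpy()
    expr = sig @ fractions.T  # genes x samples, exact mixture
    if config.noise_sd > 0:
        expr = expr * np.exp(rng.normal(0.0, config.noise_sd, size=expr.shape))

    # subtype-specific DE genes on top of the mixture: background genes plus
    # planted multiplicative shifts in each subtype
    n_bg = config.n_background_genes
    bg_names = [f"BG_{g:04d}" for g in range(n_bg)]
    de_truth: dict[str, list[str]] = {}
    if n_bg:
        bg_base = rng.uniform(20.0, 200.0, size=n_bg)
        bg = np.tile(bg_base[:, None], (1, n)) * np.exp(
            rng.normal(0.0, max(config.noise_sd, 0.05), size=(n_bg, n)))
        n_de = min(config.n_de_genes_per_subtype, n_bg // max(k, 1))
        for j in range(k):
            rows = np.arange(j * n_de, (j + 1) * n_de)
            cols = subtype == j
            if config.de_log2fc != 0 and rows.size and cols.any():
                bg[np.ix_(rows, cols)] *= 2.0 ** config.de_log2fc
            de_truth[f"subtype_{j}"] = [bg_names[r] for r in rows]
        expr = np.vstack([expr, bg])
        gene_names = list(signature.gene_ids) + bg_names
    else:
        gene_names = list(signature.gene_ids)

    expression = ExpressionMatrix(pd.DataFrame(expr, index=gene_names, columns=samples))

    betas = (config.survival_betas if config.survival_betas is not None
             else np.zeros(config.n_cell_types))
    linpred = fractions @ betas
    rate = config.baseline_hazard * np.exp(linpred)
    event_time = rng.exponential(1.0 / rate)
    censor_time = np.minimum(rng.exponential(config.censor_mean, size=n),
                             config.censoring_time)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    time = np.maximum(time, 1.0)  # day-granularity floor keeps times positive
    age = rng.integers(35, 85, size=n)
    stage = rng.choice(["I", "II", "III"], size=n, p=[0.3, 0.5, 0.2])
    clinical = SurvivalData(np.array(samples), time, event,
                            extra=pd.DataFrame({"age": age, "stage": stage},
                                               index=samples))

    mutation_rates = (config.mutation_rates if config.mutation_rates is not None
                      else {g: np.resize(r, k) for g, r in _DEFAULT_MUTATION_RATES.items()})
    records = []
    for gene, rates in mutation_rates.items():
        rates = np.asarray(rates, dtype=float)
        if rates.shape != (k,):
            raise ValueError(f"mutation rates for {gene} must have one entry per subtype")
        mutated = rng.random(n) < rates[subtype]
        for i in np.where(mutated)[0]:
            records.append((samples[i], gene, "Missense_Mutation"))
            if rng.random() < _SILENT_FRACTION:
                records.append((samples[i], gene,
                                rng.choice(["Silent", "Intron"])))
    mutations = pd.DataFrame(records or None,
                             columns=["Tumor_Sample_Barcode", "Hugo_Symbol",
                                      "Variant_Classification"])

    truth = {
        "config": {kk: (vv.tolist() if isinstance(vv, np.ndarray) else vv)
                   for kk, vv in vars(config).items()
                   if kk != "mutation_rates"},
        "mutation_rates": {g: list(map(float, np.asarray(r).ravel()))
                           for g, r in mutation_rates.items()},
        "subtype": {s: int(lab) for s, lab in zip(samples, subtype)},
        "linear_predictor": {s: float(v) for s, v in zip(samples, linpred)},
        "de_genes": de_truth,
        "survival_betas": betas.tolist(),
    }
    return SyntheticCohort(
        expression=expression,
        true_fractions=pd.DataFrame(fractions, index=samples, columns=cell_types),
        true_subtype=pd.Series(subtype, index=samples, name="subtype"),
        clinical=clinical,
        mutations=mutations,
        truth=truth,
    )


def write_cohort(cohort: SyntheticCohort, directory) -> dict[str, Path]:
    """Write expression/clinical/mutation TSVs plus a truth JSON; returns paths."""
    if cohort.expression.n_samples == 0:
        raise ValueError("refusing to write an empty cohort")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": directory / "expression.tsv",
        "clinical": directory / "clinical.tsv",
        "mutations": directory / "mutations.tsv",
        "fractions": directory / "true_fractions.tsv",
        "truth": directory / "truth.json",
    }
    cohort.expression.data.to_csv(paths["expression"], sep="\t", index_label="gene",
                                  float_format="%.12g")
    cohort.clinical.to_frame().to_csv(paths["clinical"], sep="\t", index=False,
                                      float_format="%.12g")
    cohort.mutations.to_csv(paths["mutations"], sep="\t", index=False)
    cohort.true_fractions.to_csv(paths["fractions"], sep="\t", index_label="sample",
                                 float_format="%.17g")
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=2)
    return paths


def read_cohort(directory) -> dict:
    """Read back the files written by :func:`write_cohort` (round-trip helper)."""
    directory = Path(directory)
    expression = pd.read_csv(directory / "expression.tsv", sep="\t", index_col=0)
    clinical = pd.read_csv(directory / "clinical.tsv", sep="\t")
    mutations = pd.read_csv(directory / "mutations.tsv", sep="\t")
    fractions = pd.read_csv(directory / "true_fractions.tsv", sep="\t", index_col=0)
    with open(directory / "truth.json") as fh:
        truth = json.load(fh)
    return {"expression": expression, "clinical": clinical, "mutations": mutations,
            "fractions": fractions, "truth": truth}
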