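"""Pipeline configuration with the study's parameter values as defaults.

One root seed drives every stochastic stage; per-stage seeds are derived
deterministically from it via ``numpy.random.SeedSequence`` spawning so a
single integer reproduces the whole run.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

# Ordered stage names used for deterministic per-stage seed derivation.
STAGES = ("deconvolution", "subtyping", "phenotype_genes", "signature",
          "tme_score", "survival_eval", "genomic")


@dataclass
class PipelineConfig:
    """Every stage's tunable parameters.

    Defaults are the workflow's standard settings: consensus clustering over
    k in [2, 10] with 1000 resampling repetitions, 1000-permutation
    deconvolution significance, DE at FDR < 0.05, 50 NMF runs with a
    minimum cluster membership of 10, random-forest mtry scanned over
    1-235 at 500 trees with a final forest of 100 trees, candidate genes
    at > 95% cumulative importance, and a 30-day minimum follow-up.
    """

    seed: int = 0
    min_followup_days: int = 30
    # deconvolution
    nu_grid: tuple[float, ...] = (0.25, 0.5, 0.75)
    n_permutations: int = 1000
    svr_tol: float = 1e-5
    # cell screen + consensus subtyping
    cell_screen_p: float = 0.05
    consensus_k_min: int = 2
    consensus_k_max: int = 10
    consensus_reps: int = 1000
    subsample_fraction: float = 0.8
    consensus_base_method: str = "hierarchical"
    delta_area_threshold: float = 0.1
    # differential expression
    de_fdr: float = 0.05
    max_zero_fraction: float = 0.5
    # NMF reclustering
    nmf_runs: int = 50
    nmf_rank_min: int = 2
    nmf_rank_max: int = 10
    nmf_min_membership: int = 10
    # signature building
    gene_cox_p: float = 0.05
    rf_mtry_min: int = 1
    rf_mtry_max: int = 235
    rf_ntree_search: int = 500
    rf_ntree_final: int = 100
    rf_target: str = "survival_status"
    cumulative_importance: float = 0.95
    kmeans_k: int = 3
    # downstream tests
    mutation_p: float = 0.05
    panel_fdr: float = 0.05
    auc_horizons_years: tuple[float, ...] = (3.0, 5.0)

    def __post_init__(self) -> None:
        if not (2 <= self.consensus_k_min <= self.consensus_k_max):
            raise ValueError("need 2 <= consensus_k_min <= consensus_k_max")
        if not 0 < self.subsample_fraction <= 1:
            raise ValueError("subsample_fraction must be in (0, 1]")
        if not 0 < self.cumulative_importance <= 1:
            raise ValueError("cumulative_importance must be in (0, 1]")

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed (< 2**31) derived from the root seed."""
        idx = STAGES.index(stage)
        child = np.random.SeedSequence(self.seed).spawn(len(STAGES))[idx]
        return int(child.generate_state(1)[0] % (2**31))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("nu_grid", "auc_horizons_years"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)
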