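"""End-to-end pipeline: deconvolution -> subtyping -> phenotype genes ->
signature -> TME score -> survival evaluation -> genomic association.

Every stage writes its intermediate tables into the output directory and a
JSON manifest records parameters, per-stage seeds and completion; rerunning
with the same config and seed is reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import STAGES, PipelineConfig
from .deconvolution import SignatureMatrix, cell_score_correlations, deconvolve_cohort
from .genomic import PANELS, PanelDefinition, compare_panel_expression, \
    filter_mutations, mutation_frequency_test
from .io import ExpressionMatrix
from .phenotype_genes import differential_expression, filter_expressed, \
    intersect_up_degs, nmf_recluster
from .scoring import fit_tme_model, score_samples, stratify_median
from .signature import GeneSignatureSet, RFConfig, cluster_genes, \
    compute_signature_scores, cox_screen_genes, rank_importance, select_cumulative
from .subtyping import ConsensusConfig, consensus_cluster, screen_prognostic_cells
from .survival import SurvivalData, concordance_index, cox_fit, km_estimate, \
    logrank_test, time_dependent_auc

log = logging.getLogger("tmescore")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    fractions: object = None
    cell_screen: pd.DataFrame = None
    consensus: object = None
    tmec_labels: pd.Series = None
    deg_genes: list = None
    nmf: object = None
    genec_labels: pd.Series = None
    signatures: GeneSignatureSet = None
    signature_scores: pd.DataFrame = None
    model: object = None
    score_table: pd.DataFrame = None
    evaluation: dict = field(default_factory=dict)
    panel_results: dict = field(default_factory=dict)
    mutation_results: pd.DataFrame = None
    manifest: dict = field(default_factory=dict)


def run_pipeline(expression: ExpressionMatrix, survival: SurvivalData,
                 signature_matrix: SignatureMatrix,
                 config: PipelineConfig,
                 mutations: pd.DataFrame | None = None,
                 out_dir=None, run_nmf: bool = True) -> PipelineResult:
    """Execute the full workflow on an in-memory cohort.

    ``out_dir=None`` skips writing intermediates. A stage failure raises
    :class:`StageError` naming the stage, with earlier outputs preserved in
    the written directory.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    res = PipelineResult()
    completed = []
    surv = survival.subset(expression.sample_ids)

    def _finish(stage: str) -> None:
        completed.append(stage)
        log.info("[%s] completed", stage)

    # 1. deconvolution ------------------------------------------------------
    stage = "deconvolution"
    try:
        res.fractions = deconvolve_cohort(
            expression, signature_matrix, n_perm=config.n_permutations,
            seed=config.stage_seed(stage), nu_grid=config.nu_grid,
            svr_tol=config.svr_tol)
        corr = cell_score_correlations(res.fractions)
        if out is not None:
            res.fractions.to_tsv(out / "cell_fractions.tsv")
            corr.to_csv(out / "cell_correlations.tsv", sep="\t")
    except Exception as exc:
        raise StageError(stage, exc) from exc
    _finish(stage)

    # 2. subtyping ----------------------------------------------------------
    stage = "subtyping"
    try:
        res.cell_screen = screen_prognostic_cells(res.fractions, surv,
                                                  p_threshold=config.cell_screen_p)
        selected = list(res.cell_screen.index[res.cell_screen["selected"]])
        if len(selected) < 2:
            log.warning("[%s] only %d prognostic cell types; clustering all "
                        "cell scores instead", stage, len(selected))
            selected = list(res.fractions.fractions.columns)
        cc = ConsensusConfig(k_min=config.consensus_k_min, k_max=config.consensus_k_max,
                             n_reps=config.consensus_reps,
                             subsample_fraction=config.subsample_fraction,
                             base_method=config.consensus_base_method,
                             delta_area_threshold=config.delta_area_threshold,
                             seed=config.stage_seed(stage))
        res.consensus = consensus_cluster(res.fractions.fractions[selected], cc)
        res.tmec_labels = res.consensus.labels
        if out is not None:
            res.cell_screen.to_csv(out / "cell_screen.tsv", sep="\t")
            res.tmec_labels.rename("TMEC").to_csv(out / "tmec_labels.tsv", sep="\t")
            res.consensus.delta_area.rename("delta_area").to_csv(
                out / "delta_area.tsv", sep="\t")
    except Exception as exc:
        raise StageError(stage, exc) from exc
    _finish(stage)

    # 3. phenotype genes ----------------------------------------------------
    stage = "phenotype_genes"
    try:
        labels = res.tmec_labels
        # reference subtype: best prognosis = lowest event rate among subtypes
        event_rate = {}
        for lab in sorted(labels.unique()):
            ids = labels.index[labels == lab]
            sub = surv.subset(ids)
            event_rate[lab] = sub.event.mean()
        ref = min(event_rate, key=event_rate.get)
        others = [lab for lab in sorted(labels.unique()) if lab != ref]
        de_results = []
        for lab in others:
            de = differential_expression(
                expression,
                group_a=list(labels.index[labels == ref]),
                group_b=list(labels.index[labels == lab]))
            de_results.append(de)
        inter = intersect_up_degs(de_results, fdr_threshold=config.de_fdr)
        res.deg_genes = filter_expressed(inter.genes, expression,
                                         max_zero_fraction=config.max_zero_fraction)
        if out is not None:
            for lab, de in zip(others, de_results):
                de.to_csv(out / f"de_TMEC{ref}_vs_TMEC{lab}.tsv", sep="\t")
            pd.Series(res.deg_genes, name="gene").to_csv(
                out / "deg_genes.tsv", sep="\t", index=False)
        if run_nmf and len(res.deg_genes) >= 2:
            try:
                res.nmf = nmf_recluster(
                    expression.subset_genes(res.deg_genes),
                    rank_range=(config.nmf_rank_min, config.nmf_rank_max),
                    n_runs=config.nmf_runs,
                    min_membership=config.nmf_min_membership,
                    seed=config.stage_seed(stage))
                res.genec_labels = res.nmf.labels
                if out is not None:
                    res.genec_labels.rename("GeneC").to_csv(
                        out / "genec_labels.tsv", sep="\t")
            except ValueError as exc:
                log.warning("[%s] NMF reclustering skipped: %s", stage, exc)
    except Exception as exc:
        raise StageError(stage, exc) from exc
    _finish(stage)

    # 4. signature ----------------------------------------------------------
    stage = "signature"
    try:
        deg_expr = expression.subset_genes(res.deg_genes)
        if deg_expr.n_genes == 0:
            raise ValueError("no phenotype-associated genes survived filtering")
        screened = cox_screen_genes(deg_expr, surv, p_threshold=config.gene_cox_p)
        if len(screened) < config.kmeans_k:
            log.warning("[%s] only %d genes pass the Cox screen; using all "
                        "DEGs", stage, len(screened))
            screened = list(deg_expr.gene_ids)
        screened_expr = expression.subset_genes(screened)
        if config.rf_target == "survival_status":
            target = surv.event
        elif config.rf_target == "tmec":
            target = res.tmec_labels.loc[list(expression.sample_ids)].to_numpy()
        else:
            raise ValueError(f"unknown rf_target {config.rf_target!r}")
        rf = RFConfig(mtry_min=config.rf_mtry_min, mtry_max=config.rf_mtry_max,
                      ntree_search=config.rf_ntree_search,
                      ntree_final=config.rf_ntree_final,
                      target=config.rf_target, seed=config.stage_seed(stage))
        ranking = rank_importance(screened_expr, target, rf)
        candidates = select_cumulative(ranking, fraction=config.cumulative_importance)
        k = min(config.kmeans_k, len(candidates))
        groups = cluster_genes(expression.subset_genes(candidates), k=k,
                               seed=config.stage_seed(stage))
        res.signatures = GeneSignatureSet(groups)
        res.signature_scores = compute_signature_scores(expression, res.signatures)
        if out is not None:
            ranking.to_csv(out / "importance_ranking.tsv", sep="\t")
            with open(out / "signatures.json", "w") as fh:
                json.dump(res.signatures.to_dict(), fh, indent=2)
            res.signature_scores.to_csv(out / "signature_scores.tsv", sep="\t",
                                        index_label="sample")
    except Exception as exc:
        raise StageError(stage, exc) from exc
    _finish(stage)

    # 5. TME score ----------------------------------------------------------
    stage = "tme_score"
    try:
        res.model = fit_tme_model(res.signature_scores, surv)
        table = score_samples(res.model, res.signature_scores)
        res.score_table = stratify_median(table)
        if out is not None:
            res.model.to_json(out / "tme_model.json")
            res.score_table.to_csv(out / "tme_scores.tsv", sep="\t",
                                   index_label="sample")
    except Exception as exc:
        raise StageError(stage, exc) from exc
    _finish(stage)

    # 6. survival evaluation ------------------------------------------------
    stage = "survival_eval"
    try:
        tab = res.score_table
        hi_ids = tab.index[tab["risk_group"] == "risk-h"]
        lo_ids = tab.index[tab["risk_group"] == "risk-l"]
        chi2, lr_p = logrank_test(surv.subset(lo_ids), surv.subset(hi_ids))
        hr_fit = cox_fit((tab["risk_group"] == "risk-h").to_numpy(float)[:, None],
                         surv.subset(tab.index))
        risk = tab["tme_score"].to_numpy()
        ev = {
            "logrank_chi2": chi2, "logrank_p": lr_p,
            "risk_h_vs_l_hr": float(hr_fit.hr[0]),
            "c_index": concordance_index(risk, surv.subset(tab.index)),
            "median_tme_score": tab.attrs.get("threshold"),
        }
        for years in config.auc_horizons_years:
            horizon = years * 365.0
            try:
                ev[f"auc_{years:g}y"] = time_dependent_auc(
                    risk, surv.subset(tab.index), horizon)
            except ValueError as exc:
                log.warning("[%s] AUC at %gy unavailable: %s", stage, years, exc)
        res.evaluation = ev
        if out is not None:
            with open(out / "evaluation.json", "w") as fh:
                json.dump(ev, fh, indent=2)
    except Exception as exc:
        raise StageError(stage, exc) from exc
    _finish(stage)

    # 7. genomic association ------------------------------------------------
    stage = "genomic"
    try:
        risk_groups = res.score_table["risk_group"]
        for name, genes in PANELS.items():
            try:
                res.panel_results[name] = compare_panel_expression(
                    expression, risk_groups, PanelDefinition(name, genes))
            except KeyError:
                log.info("[%s] panel %s has no genes in this cohort", stage, name)
        if mutations is not None and len(mutations):
            filtered = filter_mutations(mutations)
            res.mutation_results = mutation_frequency_test(
                filtered, risk_groups, p_threshold=config.mutation_p)
            if out is not None:
                res.mutation_results.to_csv(out / "mutation_tests.tsv", sep="\t")
        if out is not None:
            for name, df in res.panel_results.items():
                df.to_csv(out / f"panel_{name}.tsv", sep="\t")
    except Exception as exc:
        raise StageError(stage, exc) from exc
    _finish(stage)

    res.manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "stage_seeds": {s: config.stage_seed(s) for s in STAGES},
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(config).items()},
        "stages_completed": completed,
        "n_samples": int(expression.n_samples),
        "n_genes": int(expression.n_genes),
    }
    if out is not None:
        with open(out / "manifest.json", "w") as fh:
            json.dump(res.manifest, fh, indent=2)
    return res
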