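"""Gene-signature construction: Cox screen, random-forest importance
reduction, K-means gene grouping and PC1 signature scores.

The per-group signature score of sample s is

    S_j(s) = sum_i Pc1_i * Exp_i(s)

where Pc1_i is the unit-norm first-principal-component loading of gene i
within group j (genes as variables, samples as observations) and Exp_i is
the gene's centered expression.  The loading sign is fixed so it correlates
positively with the group's mean expression profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .io import ExpressionMatrix
from .survival import SurvivalData, cox_fit


def cox_screen_genes(expression: ExpressionMatrix, survival: SurvivalData,
                     p_threshold: float = 0.05) -> list[str]:
    """Retain genes with univariate Cox p below the threshold.

    Each gene is standardized before fitting so hazard ratios are per
    standard deviation.  Constant genes are skipped with a warning.
    """
    surv = survival.subset(expression.sample_ids)
    if surv.n_events < 2:
        raise ValueError("need >= 2 events for the Cox gene screen")
    selected = []
    for gene in expression.gene_ids:
        x = expression.data.loc[gene].to_numpy(dtype=float)
        sd = x.std()
        if sd == 0:
            warnings.warn(f"gene {gene!r} constant; skipped", UserWarning, stacklevel=2)
            continue
        z = (x - x.mean()) / sd
        try:
            fit = cox_fit(z[:, None], surv)
        except RuntimeError:
            warnings.warn(f"gene {gene!r}: Cox fit failed; skipped",
                          UserWarning, stacklevel=2)
            continue
        if fit.wald_p[0] < p_threshold:
            selected.append(gene)
    return selected


@dataclass
class RFConfig:
    """Random-forest feature-selection settings.

    The mtry grid is scanned at ``ntree_search`` trees and the value with
    the lowest out-of-bag error kept; the final forest uses
    ``ntree_final`` trees.  ``target`` picks what the forest predicts:
    'survival_status' (dead/alive) or a user-supplied categorical label.
    """

    mtry_min: int = 1
    mtry_max: int = 235
    ntree_search: int = 500
    ntree_final: int = 100
    target: str = "survival_status"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mtry_min < 1 or self.mtry_max < self.mtry_min:
            raise ValueError("need 1 <= mtry_min <= mtry_max")
        if self.ntree_search < 1 or self.ntree_final < 1:
            raise ValueError("ntree values must be >= 1")


def rank_importance(expression: ExpressionMatrix, target: np.ndarray,
                    config: RFConfig) -> pd.DataFrame:
    """Random-forest importance ranking of genes (samples as rows).

    Returns a DataFrame sorted by descending mean-impurity-decrease
    importance with 1-based ranks and the running normalized cumulative
    importance; the chosen mtry and its OOB error are attached as
    ``DataFrame.attrs``.
    """
    y = np.asarray(target)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("random-forest target has a single class")
    if counts.min() < 5:
        raise ValueError("each target class needs >= 5 samples")
    x = expression.data.T.to_numpy(dtype=float)  # samples x genes
    n_genes = x.shape[1]
    mtry_grid = range(config.mtry_min, min(config.mtry_max, n_genes) + 1)
    best_mtry, best_err = None, np.inf
    oob_curve = {}
    for mtry in mtry_grid:
        rf = RandomForestClassifier(n_estimators=config.ntree_search,
                                    max_features=mtry, oob_score=True,
                                    random_state=config.seed, n_jobs=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # few-tree OOB coverage warnings
            rf.fit(x, y)
        err = 1.0 - rf.oob_score_
        oob_curve[mtry] = err
        if err < best_err:
            best_mtry, best_err = mtry, err
    final = RandomForestClassifier(n_estimators=config.ntree_final,
                                   max_features=best_mtry,
                                   random_state=config.seed, n_jobs=1)
    final.fit(x, y)
    imp = final.feature_importances_
    order = np.argsort(-imp, kind="stable")
    total = imp.sum() if imp.sum() > 0 else 1.0
    out = pd.DataFrame({
        "gene": np.asarray(expression.gene_ids)[order],
        "importance": imp[order],
        "rank": np.arange(1, n_genes + 1),
        "cumulative_fraction": np.cumsum(imp[order]) / total,
    }).set_index("gene")
    out.attrs["mtry"] = int(best_mtry)
    out.attrs["oob_error"] = float(best_err)
    out.attrs["oob_curve"] = oob_curve
    return out


def select_cumulative(ranking: pd.DataFrame, fraction: float = 0.95) -> list[str]:
    """Smallest prefix of the ranking reaching the cumulative-importance fraction."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    cum = ranking["cumulative_fraction"].to_numpy()
    n_keep = int(np.searchsorted(cum, fraction, side="left")) + 1
    n_keep = min(n_keep, len(ranking))
    return list(ranking.index[:n_keep])


def cluster_genes(expression: ExpressionMatrix, k: int, seed: int = 0) -> dict[str, list[str]]:
    """Group genes by K-means on their standardized expression profiles.

    Genes are points, samples are dimensions; k-means++ with 10 restarts,
    best inertia kept.  Groups are named G1..Gk ordered by descending mean
    (raw) expression.  Empty clusters trigger a reseeded restart.
    """
    from sklearn.cluster import KMeans

    n_genes = expression.n_genes
    if k > n_genes:
        raise ValueError(f"k ({k}) exceeds number of genes ({n_genes})")
    x = expression.data.to_numpy(dtype=float)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    xz = (x - x.mean(axis=1, keepdims=True)) / sd
    for attempt in range(50):
        km = KMeans(n_clusters=k, init="k-means++", n_init=10,
                    random_state=seed + attempt)
        labels = km.fit_predict(xz)
        if len(np.unique(labels)) == k:
            break
    else:
        raise RuntimeError("K-means produced an empty cluster in 50 attempts")
    mean_expr = {lab: x[labels == lab].mean() for lab in np.unique(labels)}
    ordered = sorted(mean_expr, key=mean_expr.get, reverse=True)
    genes = np.asarray(expression.gene_ids)
    return {f"G{i + 1}": list(genes[labels == lab])
            for i, lab in enumerate(ordered)}


@dataclass
class GeneSignatureSet:
    """Disjoint gene groups with per-gene unit-norm PC1 loadings."""

    groups: dict[str, list[str]]
    loadings: dict[str, pd.Series] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, genes in self.groups.items():
            if seen & set(genes):
                raise ValueError("signature groups must be disjoint")
            seen |= set(genes)

    @property
    def group_sizes(self) -> dict[str, int]:
        return {name: len(genes) for name, genes in self.groups.items()}

    def to_dict(self) -> dict:
        return {name: {"genes": genes,
                       "loadings": (self.loadings[name].to_dict()
                                    if name in self.loadings else None)}
                for name, genes in self.groups.items()}


def compute_signature_scores(expression: ExpressionMatrix,
                             signatures: GeneSignatureSet) -> pd.DataFrame:
    """PC1 signature score per sample and group: S_j = sum_i Pc1_i * centered Exp_i.

    Loadings are the unit-norm leading eigenvector of the genes-as-variables
    covariance over samples, sign-fixed against the group's mean expression
    profile (ties toward a positive first coordinate).  Single-gene groups
    score as the gene's centered expression with a warning.  Fitted
    loadings are stored back into ``signatures.loadings``.
    """
    scores = {}
    for name, genes in signatures.groups.items():
        missing = [g for g in genes if g not in expression.data.index]
        if missing:
            raise KeyError(f"group {name}: genes absent from expression: {missing[:5]}")
        x = expression.data.loc[genes].to_numpy(dtype=float)  # genes x samples
        xc = x - x.mean(axis=1, keepdims=True)
        if len(genes) < 2:
            warnings.warn(f"group {name} has < 2 genes; score is the centered "
                          "expression of its single gene", UserWarning, stacklevel=2)
            loading = np.ones(1)
        else:
            cov = np.cov(xc)
            eigval, eigvec = np.linalg.eigh(cov)
            loading = eigvec[:, -1]
            mean_profile = x.mean(axis=1)
            centered_profile = mean_profile - mean_profile.mean()
            align = float(loading @ centered_profile)
            if align < 0 or (align == 0 and loading[0] < 0):
                loading = -loading
        loading = loading / np.linalg.norm(loading)
        signatures.loadings[name] = pd.Series(loading, index=genes)
        scores[name] = loading @ xc
    return pd.DataFrame(scores, index=expression.sample_ids)
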