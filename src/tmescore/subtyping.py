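"""Prognostic screening of cell scores and consensus clustering into TME subtypes.

Cell scores are first screened for survival association (univariate Cox on
the continuous score plus a median-split log-rank test); the selected scores
are then clustered by resampling-based consensus clustering over a range of
k, with k chosen from the relative increment of the area under the consensus
CDF (the delta-area elbow).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .deconvolution import CellFractionTable
from .survival import SurvivalData, cox_fit, logrank_test

_CDF_GRID = np.linspace(0.0, 1.0, 101)


def screen_prognostic_cells(fractions: CellFractionTable | pd.DataFrame,
                            survival: SurvivalData,
                            p_threshold: float = 0.05) -> pd.DataFrame:
    """Univariate prognostic screen of each cell-type score.

    Per cell type: Cox hazard ratio and p on the continuous score, plus a
    median-split log-rank p. A cell type is selected when its log-rank p is
    below the threshold; direction is 'unfavorable' when HR > 1.  Zero-
    variance scores are skipped with a warning.
    """
    df = fractions.fractions if isinstance(fractions, CellFractionTable) else fractions
    surv = survival.subset(df.index)
    if surv.n_events < 2:
        raise ValueError("need >= 2 events for the prognostic screen")
    rows = []
    for ct in df.columns:
        score = df[ct].to_numpy(dtype=float)
        if score.std() == 0:
            warnings.warn(f"cell type {ct!r} has zero-variance score; skipped",
                          UserWarning, stacklevel=2)
            continue
        fit = cox_fit(score[:, None], surv)
        med = np.median(score)
        hi = score > med
        if hi.sum() == 0 or (~hi).sum() == 0:
            warnings.warn(f"cell type {ct!r}: degenerate median split; skipped",
                          UserWarning, stacklevel=2)
            continue
        ids = df.index.to_numpy()
        chi2, lr_p = logrank_test(surv.subset(ids[~hi]), surv.subset(ids[hi]))
        rows.append({
            "cell_type": ct,
            "hazard_ratio": float(fit.hr[0]),
            "cox_p": float(fit.wald_p[0]),
            "logrank_p": lr_p,
            "direction": "unfavorable" if fit.hr[0] > 1 else "favorable",
            "selected": lr_p < p_threshold,
        })
    return pd.DataFrame(rows).set_index("cell_type")


@dataclass
class ConsensusConfig:
    """Resampling-consensus settings (package defaults follow ConsensusClusterPlus)."""

    k_min: int = 2
    k_max: int = 10
    n_reps: int = 1000
    subsample_fraction: float = 0.8
    base_method: str = "hierarchical"
    delta_area_threshold: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (2 <= self.k_min <= self.k_max):
            raise ValueError("need 2 <= k_min <= k_max")
        if not 0 < self.subsample_fraction <= 1:
            raise ValueError("subsample_fraction must be in (0, 1]")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.base_method not in ("hierarchical", "kmeans"):
            raise ValueError(f"unknown base method {self.base_method!r}")


@dataclass
class ConsensusResult:
    consensus_matrices: dict  # k -> samples x samples DataFrame
    cdf: pd.DataFrame  # rows: grid points, columns: k
    areas: pd.Series  # k -> area under consensus CDF
    delta_area: pd.Series  # k -> relative area increment
    chosen_k: int
    labels: pd.Series  # sample -> TMEC label (1..chosen_k)
    config: ConsensusConfig = field(repr=False, default=None)


def _base_cluster(x: np.ndarray, k: int, method: str, rng: np.random.Generator) -> np.ndarray:
    if method == "kmeans":
        km = KMeans(n_clusters=k, n_init=3, random_state=int(rng.integers(2**31)))
        return km.fit_predict(x)
    z = linkage(x, method="average", metric="euclidean")
    return fcluster(z, t=k, criterion="maxclust")


def consensus_cluster(score_matrix: pd.DataFrame, config: ConsensusConfig) -> ConsensusResult:
    """Resampling-based consensus clustering over k in [k_min, k_max].

    Each repetition subsamples the cohort, clusters it with the base method,
    and accumulates pairwise co-clustering counts normalized by co-sampling
    counts.  Scores are standardized per column before clustering.  Final
    labels come from average-linkage hierarchical clustering of
    1 - consensus at the chosen k.  Deterministic given the seed.
    """
    if score_matrix.isna().any().any():
        raise ValueError("score matrix contains missing values")
    n = score_matrix.shape[0]
    if config.k_max >= n:
        raise ValueError(f"k_max ({config.k_max}) must be < n_samples ({n})")
    x = score_matrix.to_numpy(dtype=float)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    x = (x - x.mean(axis=0)) / sd

    rng = np.random.default_rng(config.seed)
    n_sub = max(2, int(round(config.subsample_fraction * n)))
    ks = list(range(config.k_min, config.k_max + 1))
    co_cluster = {k: np.zeros((n, n)) for k in ks}
    co_sample = {k: np.zeros((n, n)) for k in ks}
    for _ in range(config.n_reps):
        for k in ks:
            idx = (np.arange(n) if n_sub == n
                   else rng.choice(n, size=n_sub, replace=False))
            labels = _base_cluster(x[idx], k, config.base_method, rng)
            same = labels[:, None] == labels[None, :]
            co_sample[k][np.ix_(idx, idx)] += 1
            co_cluster[k][np.ix_(idx, idx)] += same

    matrices, areas, cdf_cols = {}, {}, {}
    for k in ks:
        with np.errstate(invalid="ignore"):
            cons = np.where(co_sample[k] > 0, co_cluster[k] / np.maximum(co_sample[k], 1), 0.0)
        np.fill_diagonal(cons, 1.0)
        cons = (cons + cons.T) / 2.0
        matrices[k] = pd.DataFrame(cons, index=score_matrix.index,
                                   columns=score_matrix.index)
        vals = cons[np.triu_indices(n, k=1)]
        cdf = np.searchsorted(np.sort(vals), _CDF_GRID, side="right") / len(vals)
        cdf_cols[k] = cdf
        areas[k] = float(np.trapezoid(cdf, _CDF_GRID))

    areas = pd.Series(areas)
    delta = _delta_area(areas)
    chosen_k = _select_from_delta(delta, config.k_min, config.delta_area_threshold)
    labels = _labels_from_consensus(matrices[chosen_k], chosen_k)
    result = ConsensusResult(matrices, pd.DataFrame(cdf_cols, index=_CDF_GRID),
                             areas, delta, chosen_k, labels, config)
    _assert_consensus_separation(result)
    return result


def _delta_area(areas: pd.Series) -> pd.Series:
    """Relative increment of the CDF area; at k_min the raw area itself."""
    ks = list(areas.index)
    delta = {}
    for i, k in enumerate(ks):
        if i == 0:
            delta[k] = areas[k]
        else:
            prev = areas[ks[i - 1]]
            delta[k] = (areas[k] - prev) / prev if prev > 0 else 0.0
    return pd.Series(delta)


def _select_from_delta(delta: pd.Series, k_min: int, threshold: float) -> int:
    above = [k for k, d in delta.items() if d > threshold]
    return max(above) if above else k_min


def select_k(result: ConsensusResult, threshold: float | None = None) -> int:
    """Pick k at the elbow of the delta-area curve.

    The largest k whose relative CDF-area increment exceeds the threshold
    (default: the value stored in the result's config, 0.1); k_min when no
    k qualifies.
    """
    if threshold is None:
        threshold = result.config.delta_area_threshold if result.config else 0.1
    if len(result.delta_area) < 2:
        raise ValueError("need >= 2 candidate k values")
    return _select_from_delta(result.delta_area, min(result.delta_area.index), threshold)


def _labels_from_consensus(consensus: pd.DataFrame, k: int) -> pd.Series:
    dist = 1.0 - consensus.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum((dist + dist.T) / 2.0, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    raw = fcluster(z, t=k, criterion="maxclust")
    # stable renumbering 1..k by first appearance
    remap = {}
    out = np.empty_like(raw)
    for i, lab in enumerate(raw):
        out[i] = remap.setdefault(lab, len(remap) + 1)
    return pd.Series(out, index=consensus.index, name="TMEC")


def _assert_consensus_separation(result: ConsensusResult) -> None:
    """Within-cluster mean consensus must be >= between-cluster mean at chosen_k."""
    cons = result.consensus_matrices[result.chosen_k].to_numpy()
    labels = result.labels.to_numpy()
    same = labels[:, None] == labels[None, :]
    off = ~np.eye(len(labels), dtype=bool)
    within = cons[same & off]
    between = cons[~same]
    if len(within) and len(between):
        assert within.mean() >= between.mean(), (
            "consensus labels inconsistent: between-cluster consensus exceeds "
            "within-cluster consensus")
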