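"""Immune-cell deconvolution of bulk expression by nu-support-vector regression.

Implements the CIBERSORT-style scoring recipe: the mixture and the reference
signature are z-standardized, a linear-kernel nu-SVR is fit for each nu in a
small grid, the nu minimizing reconstruction RMSE is kept, negative cell
coefficients are clipped to zero and the rest normalized to proportions.
Per-sample significance comes from a gene-label permutation null on the
reconstruction correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import NuSVR

from .io import ExpressionMatrix

DEFAULT_NU_GRID = (0.25, 0.5, 0.75)


class InsufficientOverlapError(ValueError):
    """Mixture shares too few genes with the signature matrix."""


@dataclass
class SignatureMatrix:
    """Genes x cell-types nonnegative reference profiles (an LM22-like matrix)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValueError("duplicate gene ids in signature matrix")
        if self.data.shape[1] < 2:
            raise ValueError("signature matrix needs >= 2 cell types")
        vals = self.data.to_numpy(dtype=float)
        if not np.isfinite(vals).all() or (vals < 0).any():
            raise ValueError("signature values must be finite and nonnegative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def cell_types(self) -> pd.Index:
        return self.data.columns

    @property
    def n_cell_types(self) -> int:
        return self.data.shape[1]

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene")


@dataclass
class CellFractionTable:
    """Per-sample cell-type proportions with fit statistics.

    ``fractions`` rows are nonnegative and sum to 1 (or are all zero when no
    cell type received positive weight); ``p_value`` comes from the
    permutation null and lies in [1/(n_perm+1), 1].
    """

    fractions: pd.DataFrame  # samples x cell types
    rmse: pd.Series
    corr: pd.Series
    p_value: pd.Series
    n_permutations: int

    def __post_init__(self) -> None:
        f = self.fractions.to_numpy()
        assert (f >= -1e-12).all()
        sums = f.sum(axis=1)
        assert np.all((np.abs(sums - 1) < 1e-9) | (sums == 0))

    def to_tsv(self, path) -> None:
        out = self.fractions.copy()
        out["P-value"] = self.p_value
        out["Correlation"] = self.corr
        out["RMSE"] = self.rmse
        out.to_csv(path, sep="\t", index_label="sample")


def _standardize_system(mixture: pd.Series, signature: SignatureMatrix):
    """Restrict to shared genes; z-score mixture, globally standardize signature."""
    shared = signature.gene_ids.intersection(mixture.index)
    if len(shared) < 0.5 * len(signature.gene_ids):
        raise InsufficientOverlapError(
            f"only {len(shared)}/{len(signature.gene_ids)} signature genes "
            "present in mixture (need >= 50%)")
    x = signature.data.loc[shared].to_numpy(dtype=float)
    y = mixture.loc[shared].to_numpy(dtype=float)
    x = (x - x.mean()) / x.std()
    y_sd = y.std()
    if y_sd == 0:
        raise ValueError("mixture vector is constant over signature genes")
    y = (y - y.mean()) / y_sd
    return x, y


def _svr_fractions(x: np.ndarray, y: np.ndarray, nu_grid,
                   tol: float = 1e-5) -> tuple[np.ndarray, float, float]:
    """Fit nu-SVR per nu, keep min-RMSE solution; returns (fractions, rmse, corr)."""
    best = None
    for nu in nu_grid:
        model = NuSVR(nu=nu, kernel="linear", C=1.0, tol=tol)
        model.fit(x, y)
        w = model.coef_.ravel()
        recon = x @ w  # no intercept, per the published recipe
        rmse = float(np.sqrt(np.mean((recon - y) ** 2)))
        corr = float(np.corrcoef(recon, y)[0, 1]) if recon.std() > 0 else 0.0
        if best is None or rmse < best[1]:
            best = (w, rmse, corr)
    w, rmse, corr = best
    w = np.clip(w, 0.0, None)
    total = w.sum()
    if total <= 0:
        warnings.warn("all SVR coefficients non-positive; returning all-zero "
                      "fractions", UserWarning, stacklevel=3)
        return np.zeros_like(w), rmse, corr
    return w / total, rmse, corr


def deconvolve_sample(mixture: pd.Series, signature: SignatureMatrix,
                      nu_grid=DEFAULT_NU_GRID,
                      svr_tol: float = 1e-5) -> tuple[np.ndarray, float, float]:
    """Estimate cell-type proportions for one bulk mixture.

    Returns (fraction vector over signature cell types, RMSE, Pearson r of
    the reconstruction), all on the standardized scale.  Requires at least
    half of the signature genes in the mixture, linear-scale values.
    """
    x, y = _standardize_system(mixture, signature)
    return _svr_fractions(x, y, nu_grid, tol=svr_tol)


def permutation_p(mixture: pd.Series, signature: SignatureMatrix, n_perm: int,
                  seed: int, nu_grid=DEFAULT_NU_GRID,
                  svr_tol: float = 1e-5) -> float:
    """Permutation p-value for one mixture's deconvolution fit.

    The null statistic is the reconstruction Pearson correlation after
    randomly permuting the mixture's gene values; the add-one estimator
    p = (1 + #{null >= observed}) / (n_perm + 1) never returns 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    _, _, observed = deconvolve_sample(mixture, signature, nu_grid, svr_tol=svr_tol)
    values = mixture.to_numpy(dtype=float)
    exceed = 0
    for _ in range(n_perm):
        perm = pd.Series(rng.permutation(values), index=mixture.index)
        try:
            _, _, null_corr = deconvolve_sample(perm, signature, nu_grid,
                                                svr_tol=svr_tol)
        except ValueError:
            null_corr = 0.0
        if null_corr >= observed:
            exceed += 1
    return (1 + exceed) / (n_perm + 1)


def deconvolve_cohort(expression: ExpressionMatrix, signature: SignatureMatrix,
                      n_perm: int = 1000, seed: int = 0,
                      nu_grid=DEFAULT_NU_GRID,
                      svr_tol: float = 1e-5) -> CellFractionTable:
    """Deconvolve every sample of a cohort; permutation p per sample.

    ``n_perm=0`` skips the permutation test (p-values NaN) for pipelines
    that only need the fractions.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    rows, rmses, corrs, pvals = {}, {}, {}, {}
    failures = {}
    for sample in expression.sample_ids:
        mixture = expression.data[sample]
        try:
            frac, rmse, corr = deconvolve_sample(mixture, signature, nu_grid,
                                                 svr_tol=svr_tol)
        except ValueError as exc:
            failures[sample] = str(exc)
            continue
        rows[sample] = frac
        rmses[sample], corrs[sample] = rmse, corr
        if n_perm > 0:
            pvals[sample] = permutation_p(mixture, signature, n_perm,
                                          seed=int(rng.integers(2**31)),
                                          nu_grid=nu_grid, svr_tol=svr_tol)
        else:
            pvals[sample] = np.nan
    if not rows:
        raise RuntimeError(f"deconvolution failed for every sample: {failures}")
    if failures:
        warnings.warn(f"deconvolution failed for {len(failures)} samples: "
                      f"{list(failures)[:5]}", UserWarning, stacklevel=2)
    fractions = pd.DataFrame.from_dict(rows, orient="index",
                                       columns=list(signature.cell_types))
    return CellFractionTable(fractions, pd.Series(rmses), pd.Series(corrs),
                             pd.Series(pvals), n_permutations=n_perm)


def cell_score_correlations(fractions: CellFractionTable | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation of cell-type scores across samples.

    Constant columns yield NaN rows/columns with a warning rather than a
    silent zero.
    """
    df = fractions.fractions if isinstance(fractions, CellFractionTable) else fractions
    if df.shape[0] < 3:
        raise ValueError("need >= 3 samples for cell-score correlations")
    constant = df.columns[df.std(axis=0) == 0]
    if len(constant):
        warnings.warn(f"constant cell-score columns (correlation undefined): "
                      f"{list(constant)}", UserWarning, stacklevel=2)
    corr = df.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    corr.loc[constant, :] = np.nan
    corr.loc[:, constant] = np.nan
    return corr
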