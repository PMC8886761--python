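"""Expression-matrix container, file readers/writers, and cohort preprocessing rules.

Expression values are genes x samples in linear (anti-log) scale. Duplicate
gene rows are collapsed by median on read, and samples with less than 30
days of follow-up are dropped before any survival modeling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survival import SurvivalData

log = logging.getLogger("tmescore")


@dataclass
class ExpressionMatrix:
    """Genes x samples nonnegative expression matrix with unique gene symbols."""

    data: pd.DataFrame
    scale_tag: str = "linear"

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dups[:5])}")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        vals = self.data.to_numpy()
        if not np.isfinite(vals).all():
            raise ValueError("expression values must be finite")
        if (vals < 0).any():
            raise ValueError("expression values must be nonnegative (linear scale)")

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.data.index]
        return ExpressionMatrix(self.data.loc[genes], self.scale_tag)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(samples)], self.scale_tag)


def read_expression(path, collapse: str = "median") -> ExpressionMatrix:
    """Read a TSV (first column 'gene') or GCT expression file.

    Duplicate gene rows are collapsed by ``collapse``: 'median' (default),
    'max', or 'error' to refuse duplicated symbols.  Values must be
    nonnegative; a matrix whose maximum is below 50 triggers a log-scale
    warning because downstream deconvolution assumes linear mixing.
    """
    if collapse not in ("median", "max", "error"):
        raise ValueError(f"unknown collapse rule: {collapse!r}")
    with open(path) as fh:
        first = fh.readline()
    try:
        if first.startswith("#1.2"):
            df = pd.read_csv(path, sep="\t", skiprows=2, index_col=0)
            df = df.drop(columns=[c for c in ("Description",) if c in df.columns])
        else:
            df = pd.read_csv(path, sep="\t", index_col=0)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"malformed expression file {path}: {exc}") from exc
    if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
        bad = [c for c, dt in df.dtypes.items() if not np.issubdtype(dt, np.number)]
        raise ValueError(f"non-numeric expression columns: {bad}")
    if (df.to_numpy() < 0).any():
        raise ValueError("negative expression values; linear-scale input required")
    if df.index.duplicated().any():
        dup_genes = df.index[df.index.duplicated()].unique()
        if collapse == "error":
            raise ValueError(f"duplicate gene rows: {list(dup_genes[:5])}")
        agg = "median" if collapse == "median" else "max"
        log.info("collapsing %d duplicated gene symbols by %s", len(dup_genes), agg)
        df = df.groupby(level=0, sort=False).agg(agg)
    if df.to_numpy().max() < 50:
        warnings.warn("maximum expression value < 50: input may be log-scale; "
                      "linear scale expected", UserWarning, stacklevel=2)
    return ExpressionMatrix(df)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene")


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("sample", "os_days", "os_event"):
        if col not in df.columns:
            raise ValueError(f"clinical table missing required column {col!r}")
    return df


def apply_followup_filter(clinical: pd.DataFrame, min_days: int = 30) -> SurvivalData:
    """Drop samples with follow-up below ``min_days`` or missing time/event.

    The boundary is inclusive: exactly ``min_days`` of follow-up is retained.
    """
    n0 = len(clinical)
    ok = clinical["os_days"].notna() & clinical["os_event"].notna()
    n_missing = int((~ok).sum())
    kept = clinical[ok & (clinical["os_days"] >= min_days)]
    n_short = n0 - n_missing - len(kept)
    if n_missing or n_short:
        log.info("follow-up filter: dropped %d missing, %d with < %d days",
                 n_missing, n_short, min_days)
    if len(kept) == 0:
        raise ValueError("no samples remain after follow-up filter")
    return SurvivalData.from_frame(kept)


def read_mutations(path) -> pd.DataFrame:
    """Read a MAF-subset TSV with Tumor_Sample_Barcode, Hugo_Symbol, Variant_Classification."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"mutation table missing columns: {missing}")
    return df[required]


def read_signature_matrix(path):
    from .deconvolution import SignatureMatrix
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SignatureMatrix(df)
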