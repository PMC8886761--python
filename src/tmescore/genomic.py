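"""Genomic and immune-panel associations of the TME risk groups.

Mutation tables (MAF-subset) are stripped of Silent/Intron records,
collapsed to binary mutated/wild per sample-gene, and tested per gene with
a two-sided Fisher exact test between risk groups.  Immune-gene panels
(activation, checkpoint, TGF-beta/EMT) are compared between groups with
Mann-Whitney U (two groups) or Kruskal-Wallis (more), BH-adjusted across
the panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix
from .survival import benjamini_hochberg

# Immune gene panels used for risk-group expression comparisons.
PANELS: dict[str, list[str]] = {
    "activation": ["CD8A", "IFNG", "GZMA", "TBX2", "PRF1", "CXCL9", "TNF",
                   "GZMB", "CXCL10"],
    "checkpoint": ["HAVCR2", "LAG3", "PDCD1LG2", "CD274", "IDO1", "CTLA4",
                   "PDCD1"],
    "tgf_emt": ["TWIST1", "COL4A1", "SMAD9", "ZEB1", "TGFBR2", "CLDN3",
                "ACTA2", "VIM"],
}

DEFAULT_EXCLUDED_CLASSES = frozenset({"silent", "intron"})

# MAF variant-classification vocabulary for sanity warnings
_KNOWN_CLASSES = {
    "missense_mutation", "nonsense_mutation", "silent", "intron", "splice_site",
    "frame_shift_del", "frame_shift_ins", "in_frame_del", "in_frame_ins",
    "nonstop_mutation", "translation_start_site", "3'utr", "5'utr",
    "3'flank", "5'flank", "rna", "igr", "targeted_region",
}


@dataclass
class PanelDefinition:
    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("panel must contain at least one gene")


def filter_mutations(table: pd.DataFrame,
                     excluded=DEFAULT_EXCLUDED_CLASSES) -> pd.DataFrame:
    """Drop silent/intronic records and collapse to one record per sample-gene.

    Classification matching is case-insensitive; unknown classification
    strings are retained with a warning naming them.  Idempotent.
    """
    if "Variant_Classification" not in table.columns:
        raise ValueError("mutation table lacks Variant_Classification column")
    if table.empty:
        return table.copy()
    excluded = {e.lower() for e in excluded}
    cls = table["Variant_Classification"].str.lower()
    unknown = sorted(set(cls) - _KNOWN_CLASSES - excluded)
    if unknown:
        warnings.warn(f"unknown variant classifications retained: {unknown}",
                      UserWarning, stacklevel=2)
    kept = table[~cls.isin(excluded)]
    return (kept.drop_duplicates(subset=["Tumor_Sample_Barcode", "Hugo_Symbol"])
            .reset_index(drop=True))


def mutation_frequency_test(table: pd.DataFrame, risk_groups: pd.Series,
                            p_threshold: float = 0.05) -> pd.DataFrame:
    """Per-gene two-sided Fisher exact test of mutation frequency by risk group.

    ``risk_groups`` maps sample -> 'risk-h'/'risk-l'.  Every mutated sample
    must be mapped; results are sorted by p with 2x2 counts and odds ratio.
    """
    unmapped = sorted(set(table["Tumor_Sample_Barcode"]) - set(risk_groups.index))
    if unmapped:
        raise ValueError(f"mutation samples without a risk group: {unmapped[:5]}")
    groups = risk_groups.astype(str)
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 risk groups, got {levels}")
    hi = groups.index[groups == "risk-h"] if "risk-h" in levels else groups.index[groups == levels[0]]
    lo = groups.index[groups == "risk-l"] if "risk-l" in levels else groups.index[groups == levels[1]]
    rows = []
    for gene, sub in table.groupby("Hugo_Symbol"):
        mutated = set(sub["Tumor_Sample_Barcode"])
        a = len(mutated & set(hi))  # mutated, risk-h
        b = len(hi) - a
        c = len(mutated & set(lo))  # mutated, risk-l
        d = len(lo) - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append({"gene": gene, "mut_risk_h": a, "wt_risk_h": b,
                     "mut_risk_l": c, "wt_risk_l": d,
                     "odds_ratio": odds, "fisher_p": p,
                     "selected": p < p_threshold})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    return out.sort_values("fisher_p", kind="stable").set_index("gene")


def compare_panel_expression(expression: ExpressionMatrix, groups: pd.Series,
                             panel: PanelDefinition) -> pd.DataFrame:
    """Nonparametric per-gene comparison of panel expression between groups.

    Two groups: Mann-Whitney U; more: Kruskal-Wallis.  BH FDR across the
    panel's present genes; group medians and the higher-median group are
    reported.  Absent panel genes are listed in a warning, not fatal.
    """
    groups = groups.loc[[s for s in groups.index if s in expression.sample_ids]]
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("need >= 2 groups for panel comparison")
    present = [g for g in panel.genes if g in expression.data.index]
    absent = sorted(set(panel.genes) - set(present))
    if absent:
        warnings.warn(f"panel {panel.name!r}: genes absent from expression: "
                      f"{absent}", UserWarning, stacklevel=2)
    if not present:
        raise KeyError(f"no panel genes present for panel {panel.name!r}")
    rows = []
    for gene in present:
        expr = expression.data.loc[gene, groups.index]
        by_group = [expr[groups == lev].to_numpy(dtype=float) for lev in levels]
        medians = {f"median_{lev}": float(np.median(v)) for lev, v in zip(levels, by_group)}
        if all(np.ptp(np.concatenate(by_group)) == 0 for _ in (0,)):
            stat, p = 0.0, 1.0
        elif len(levels) == 2:
            stat, p = stats.mannwhitneyu(by_group[0], by_group[1],
                                         alternative="two-sided")
        else:
            stat, p = stats.kruskal(*by_group)
        direction = max(zip(levels, by_group), key=lambda t: np.median(t[1]))[0]
        rows.append({"gene": gene, **medians, "statistic": float(stat),
                     "p": float(p), "higher_in": direction})
    out = pd.DataFrame(rows).set_index("gene")
    out["fdr"] = benjamini_hochberg(out["p"].to_numpy())
    assert (out["fdr"] >= out["p"] - 1e-15).all()
    return out
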