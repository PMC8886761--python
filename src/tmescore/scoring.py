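"""TME score: multivariate Cox weighting of PC1 signature scores.

TME score(s) = sum_g alpha_g * PC1_g(s), where alpha_g is the group's
multivariate Cox coefficient.  Samples above the cohort median score are
labeled risk-h, the rest (including exact ties at the median) risk-l.
External linear gene signatures are scored the same way for model
comparison.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix
from .survival import SurvivalData, cox_fit


@dataclass
class TMEScoreModel:
    alphas: pd.Series  # per-group Cox coefficient
    fit_metadata: dict = field(default_factory=dict)

    @property
    def group_names(self) -> list[str]:
        return list(self.alphas.index)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"alphas": self.alphas.to_dict(),
                       "fit_metadata": self.fit_metadata}, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "TMEScoreModel":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(pd.Series(raw["alphas"]), raw.get("fit_metadata", {}))


@dataclass
class LinearGeneSignature:
    """A published risk model: gene -> coefficient, applied to standardized expression."""

    name: str
    terms: dict[str, float]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("a linear signature needs at least one term")
        if not all(np.isfinite(list(self.terms.values()))):
            raise ValueError("signature coefficients must be finite")

    @classmethod
    def from_json(cls, path) -> "LinearGeneSignature":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(raw["name"], {g: float(c) for g, c in raw["terms"].items()})


def fit_tme_model(scores: pd.DataFrame, survival: SurvivalData) -> TMEScoreModel:
    """Multivariate Cox fit of survival on all signature-group scores jointly."""
    surv = survival.subset(scores.index)
    if surv.n_events < 2:
        raise ValueError("need >= 2 events to fit the TME model")
    x = scores.to_numpy(dtype=float)
    if x.shape[1] > 1:
        cond = np.linalg.cond(x - x.mean(axis=0))
        if cond > 1e8:
            raise ValueError(f"signature scores nearly collinear (condition "
                             f"number {cond:.3g}); groups: {list(scores.columns)}")
    fit = cox_fit(scores, surv)
    meta = {"n_iter": fit.n_iter, "loglik": fit.loglik, "ties_method": fit.ties_method,
            "se": dict(zip(scores.columns, fit.se.tolist())),
            "wald_p": dict(zip(scores.columns, fit.wald_p.tolist()))}
    return TMEScoreModel(pd.Series(fit.betas, index=scores.columns), meta)


def score_samples(model: TMEScoreModel, scores: pd.DataFrame) -> pd.DataFrame:
    """TME score per sample: the dot product of PC1 scores with the alphas."""
    missing = [g for g in model.group_names if g not in scores.columns]
    if missing:
        raise ValueError(f"score table missing signature groups: {missing}")
    tme = scores[model.group_names].to_numpy() @ model.alphas.to_numpy()
    return pd.DataFrame({"tme_score": tme}, index=scores.index)


def stratify_median(table: pd.DataFrame) -> pd.DataFrame:
    """Median split into risk-h / risk-l; ties at the median go to risk-l."""
    if len(table) < 2:
        raise ValueError("need >= 2 samples to stratify")
    s = table["tme_score"].to_numpy(dtype=float)
    if np.all(s == s[0]):
        raise ValueError("all TME scores identical; median stratification degenerate")
    med = float(np.median(s))
    out = table.copy()
    out["risk_group"] = np.where(s > med, "risk-h", "risk-l")
    out.attrs["threshold"] = med
    return out


def score_linear_signature(expression: ExpressionMatrix,
                           signature: LinearGeneSignature) -> pd.Series:
    """Risk score of an external linear model on per-gene-standardized expression."""
    present = [g for g in signature.terms if g in expression.data.index]
    missing = sorted(set(signature.terms) - set(present))
    if not present:
        raise KeyError(f"no signature genes present in expression: {missing}")
    if missing:
        warnings.warn(f"signature {signature.name!r}: missing genes {missing}",
                      UserWarning, stacklevel=2)
    x = expression.data.loc[present].to_numpy(dtype=float)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=1, keepdims=True)) / sd
    coefs = np.array([signature.terms[g] for g in present])
    return pd.Series(coefs @ z, index=expression.sample_ids,
                     name=signature.name)
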