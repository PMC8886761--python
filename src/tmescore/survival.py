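"""Survival-analysis engine: Kaplan-Meier, log-rank, Cox PH, C-index, time-dependent AUC.

All downstream prognostic statistics in the package flow through this module.
The Cox model is fit by Newton-Raphson on the partial likelihood with Efron
(default) or Breslow handling of tied event times.  The time-dependent ROC
area uses the inverse-probability-of-censoring-weighted (IPCW)
cumulative/dynamic estimator, with the censoring distribution estimated by
the reverse Kaplan-Meier method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class ConvergenceError(RuntimeError):
    """Raised when a partial-likelihood maximization fails to converge."""


@dataclass
class SurvivalData:
    """Per-sample follow-up time (days, strictly positive) and event indicator (0/1).

    ``extra`` carries optional clinical covariates (age, stage, ...) aligned
    to ``sample_ids``; it is never used by the estimators here.
    """

    sample_ids: np.ndarray
    time: np.ndarray
    event: np.ndarray
    extra: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.shape != self.event.shape or self.time.shape != self.sample_ids.shape:
            raise ValueError("sample_ids, time and event must have equal length")
        if np.any(~np.isfinite(self.time)) or np.any(self.time <= 0):
            raise ValueError("survival times must be finite and strictly positive")
        if not np.isin(self.event, [0, 1]).all():
            raise ValueError("event indicators must be 0 or 1")
        if len(np.unique(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids in survival data")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, sample_col: str = "sample",
                   time_col: str = "os_days", event_col: str = "os_event") -> "SurvivalData":
        extra_cols = [c for c in frame.columns if c not in (sample_col, time_col, event_col)]
        extra = frame.set_index(sample_col)[extra_cols] if extra_cols else None
        return cls(frame[sample_col].to_numpy(), frame[time_col].to_numpy(),
                   frame[event_col].to_numpy(), extra=extra)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"sample": self.sample_ids, "os_days": self.time,
                            "os_event": self.event})
        if self.extra is not None:
            out = out.merge(self.extra, left_on="sample", right_index=True, how="left")
        return out

    def subset(self, ids) -> "SurvivalData":
        """Reorder/restrict to ``ids`` (which must all be present)."""
        pos = pd.Index(self.sample_ids).get_indexer(ids)
        if (pos < 0).any():
            missing = np.asarray(ids)[pos < 0]
            raise KeyError(f"samples absent from survival data: {list(missing[:5])}")
        extra = self.extra.iloc[pos] if self.extra is not None else None
        return SurvivalData(self.sample_ids[pos], self.time[pos], self.event[pos], extra=extra)


@dataclass
class KMCurve:
    """Product-limit survival estimate as a right-continuous step function."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def __post_init__(self) -> None:
        assert np.all(np.diff(self.survival) <= 1e-12), "KM curve must be non-increasing"
        assert np.all((self.survival >= -1e-12) & (self.survival <= 1 + 1e-12))

    def _eval(self, t, side: str) -> np.ndarray:
        if len(self.event_times) == 0:
            out = np.ones_like(np.atleast_1d(t), dtype=float)
        else:
            idx = np.searchsorted(self.event_times, np.atleast_1d(t), side=side) - 1
            out = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])
        return out if np.ndim(t) else float(out[0])

    def evaluate(self, t: float | np.ndarray) -> np.ndarray:
        """S(t); 1 before the first event time."""
        return self._eval(t, "right")

    def evaluate_left(self, t: float | np.ndarray) -> np.ndarray:
        """S(t-): left-continuous version, used for IPCW weights."""
        return self._eval(t, "left")


@dataclass
class CoxFit:
    betas: np.ndarray
    se: np.ndarray
    loglik: float
    ties_method: str
    converged: bool
    n_iter: int
    names: list[str] = field(default_factory=list)

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.betas)

    @property
    def wald_z(self) -> np.ndarray:
        return self.betas / self.se

    @property
    def wald_p(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.wald_z))


def km_estimate(data: SurvivalData) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    A censored-only cohort yields a flat curve at 1 (no event times).
    """
    if len(data) < 1:
        raise ValueError("at least one sample required")
    order = np.argsort(data.time, kind="stable")
    t, e = data.time[order], data.event[order]
    ev_times = np.unique(t[e == 1])
    n = len(t)
    surv, at_risk = [], []
    s = 1.0
    for tt in ev_times:
        r = int(np.sum(t >= tt))
        d = int(np.sum((t == tt) & (e == 1)))
        s *= 1.0 - d / r
        surv.append(s)
        at_risk.append(r)
    return KMCurve(ev_times, np.asarray(surv, dtype=float), np.asarray(at_risk, dtype=int))


def censoring_km(data: SurvivalData) -> KMCurve:
    """Reverse Kaplan-Meier estimate of the censoring distribution G(t).

    Treats censorings as 'events'; at tied times, deaths are considered to
    precede censorings, so the at-risk set for a censoring at t excludes
    nobody who died at t.  Standard convention for IPCW weights.
    """
    t = data.time
    c = 1 - data.event
    cens_times = np.unique(t[c == 1])
    surv, at_risk = [], []
    s = 1.0
    for tt in cens_times:
        r = int(np.sum(t >= tt))
        d = int(np.sum((t == tt) & (c == 1)))
        s *= 1.0 - d / r
        surv.append(s)
        at_risk.append(r)
    return KMCurve(cens_times, np.asarray(surv, dtype=float), np.asarray(at_risk, dtype=int))


def logrank_test(group_a: SurvivalData, group_b: SurvivalData) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p) with 1 df.

    Identical groups give chi-square 0, p exactly 1.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be nonempty")
    if group_a.n_events + group_b.n_events == 0:
        raise ValueError("log-rank test requires at least one event")
    times = np.concatenate([group_a.time, group_b.time])
    events = np.concatenate([group_a.event, group_b.event])
    grp = np.concatenate([np.zeros(len(group_a)), np.ones(len(group_b))])
    ev_times = np.unique(times[events == 1])
    o_minus_e = 0.0
    var = 0.0
    for tt in ev_times:
        at_risk = times >= tt
        n = at_risk.sum()
        n1 = (at_risk & (grp == 0)).sum()
        dead = (times == tt) & (events == 1)
        d = dead.sum()
        d1 = (dead & (grp == 0)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def _cox_loglik_grad_hess(beta: np.ndarray, x: np.ndarray, time: np.ndarray,
                          event: np.ndarray, ties: str) -> tuple[float, np.ndarray, np.ndarray]:
    """Partial log-likelihood, score and negative Hessian (information).

    Iterates distinct event times from latest to earliest, accumulating the
    risk-set sums S0 = sum exp(eta), S1 = sum x exp(eta), S2 = sum xx' exp(eta).
    """
    p = x.shape[1]
    order = np.argsort(-time, kind="stable")
    xs, ts, es = x[order], time[order], event[order]
    eta = xs @ beta
    w = np.exp(eta)
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    s0, s1 = 0.0, np.zeros(p)
    s2 = np.zeros((p, p))
    i, n = 0, len(ts)
    while i < n:
        t = ts[i]
        j = i
        while j < n and ts[j] == t:
            s0 += w[j]
            s1 += w[j] * xs[j]
            s2 += w[j] * np.outer(xs[j], xs[j])
            j += 1
        dead = np.arange(i, j)[es[i:j] == 1]
        d = len(dead)
        if d:
            xd = xs[dead]
            sum_eta_d = eta[dead].sum()
            if ties == "breslow" or d == 1:
                ll += sum_eta_d - d * np.log(s0)
                grad += xd.sum(axis=0) - d * s1 / s0
                info += d * (s2 / s0 - np.outer(s1 / s0, s1 / s0))
            else:  # efron
                wd = w[dead]
                s0d = wd.sum()
                s1d = (wd[:, None] * xd).sum(axis=0)
                s2d = (wd[:, None, None] * np.einsum("ij,ik->ijk", xd, xd)).sum(axis=0)
                ll += sum_eta_d
                grad += xd.sum(axis=0)
                for l in range(d):
                    f = l / d
                    a0 = s0 - f * s0d
                    a1 = s1 - f * s1d
                    a2 = s2 - f * s2d
                    ll -= np.log(a0)
                    grad -= a1 / a0
                    info += a2 / a0 - np.outer(a1 / a0, a1 / a0)
        i = j
    return ll, grad, info


def cox_fit(covariates: np.ndarray | pd.DataFrame, data: SurvivalData,
            ties: str = "efron", max_iter: int = 50, tol: float = 1e-9) -> CoxFit:
    """Cox proportional-hazards fit by Newton-Raphson.

    Parameters
    ----------
    covariates : (n_samples, p) matrix, no missing values.
    ties : 'efron' (default) or 'breslow'.

    Raises
    ------
    ValueError for rank-deficient covariates or < 2 events;
    ConvergenceError for monotone likelihood (perfect separation) or
    failure to converge within ``max_iter``.
    """
    names = list(covariates.columns) if isinstance(covariates, pd.DataFrame) else []
    x = np.asarray(covariates, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if np.any(~np.isfinite(x)):
        raise ValueError("covariates contain missing or non-finite values")
    if data.n_events < 2:
        raise ValueError("Cox fit requires at least 2 events")
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown ties method: {ties!r}")
    if x.shape[1] > 1 and np.linalg.matrix_rank(x - x.mean(axis=0)) < x.shape[1]:
        raise ValueError("covariate matrix is rank deficient (collinear columns)")

    beta = np.zeros(x.shape[1])
    ll_old = -np.inf
    for it in range(1, max_iter + 1):
        ll, grad, info = _cox_loglik_grad_hess(beta, x, data.time, data.event, ties)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular information matrix in Cox fit") from exc
        # step-halving keeps the likelihood ascent monotone
        halvings = 0
        while halvings < 10:
            ll_new = _cox_loglik_grad_hess(beta + step, x, data.time, data.event, ties)[0]
            if ll_new >= ll - 1e-12:
                break
            step /= 2.0
            halvings += 1
        beta = beta + step
        if not np.all(np.isfinite(beta)):
            raise ConvergenceError(
                "non-finite coefficients: monotone partial likelihood, "
                "likely perfect separation of events by a covariate")
        if np.max(np.abs(beta)) > 50:
            raise ConvergenceError(
                "diverging coefficients (|beta| > 50): monotone partial likelihood, "
                "likely perfect separation of events by a covariate")
        if np.max(np.abs(step)) < tol:
            ll, grad, info = _cox_loglik_grad_hess(beta, x, data.time, data.event, ties)
            se = np.sqrt(np.diag(np.linalg.inv(info)))
            return CoxFit(beta, se, float(ll), ties, True, it, names)
        ll_old = ll
    raise ConvergenceError(f"Cox fit did not converge in {max_iter} iterations "
                           f"(last step {np.max(np.abs(step)):.3g})")


def concordance_index(risk: np.ndarray, data: SurvivalData) -> float:
    """Harrell's C over usable pairs.

    A pair (i, j) is usable when the sample with the shorter time had an
    event, or when times tie with exactly one event.  Concordant means the
    higher risk score failed earlier; risk ties count 0.5.
    """
    r = np.asarray(risk, dtype=float)
    if np.any(~np.isfinite(r)):
        raise ValueError("risk scores must be finite")
    t, e = data.time, data.event
    ti, tj = t[:, None], t[None, :]
    ri, rj = r[:, None], r[None, :]
    ei, ej = e[:, None].astype(bool), e[None, :].astype(bool)
    usable = (ei & (ti < tj)) | (ei & ~ej & (ti == tj))
    n_usable = usable.sum()
    if n_usable == 0:
        raise ValueError("no usable pairs for concordance")
    conc = usable & (ri > rj)
    tied = usable & (ri == rj)
    return float((conc.sum() + 0.5 * tied.sum()) / n_usable)


def time_dependent_auc(risk: np.ndarray, data: SurvivalData, horizon: float) -> float:
    """IPCW cumulative/dynamic AUC at ``horizon`` (days).

    Cases are samples with an event at or before the horizon; controls are
    samples still at risk after it.  Case weights are 1/G(t_i-) from the
    reverse-KM censoring estimate; the constant control weight 1/G(horizon)
    cancels.  With no censoring before the horizon this reduces to the plain
    binary AUC of event-by-horizon against the risk score.
    """
    r = np.asarray(risk, dtype=float)
    t, e = data.time, data.event
    if horizon > t.max():
        raise ValueError("horizon exceeds observed follow-up")
    cases = (t <= horizon) & (e == 1)
    controls = t > horizon
    if cases.sum() == 0 or controls.sum() == 0:
        raise ValueError("need at least one case and one control at the horizon")
    g = censoring_km(data)
    w = 1.0 / np.maximum(g.evaluate_left(t[cases]), 1e-12)
    rc, rk = r[cases], r[controls]
    greater = (rc[:, None] > rk[None, :]).sum(axis=1)
    ties = (rc[:, None] == rk[None, :]).sum(axis=1)
    num = float(np.sum(w * (greater + 0.5 * ties)))
    den = float(w.sum() * len(rk))
    return num / den


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values; NaNs are passed through untested."""
    p = np.asarray(pvals, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    ps = p[ok]
    m = len(ps)
    if m == 0:
        return out
    order = np.argsort(ps, kind="stable")
    ranked = ps[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out
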