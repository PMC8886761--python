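"""Survival engine tests: closed-form oracles plus lifelines/scikit-survival
cross-checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tmescore.survival import (ConvergenceError, SurvivalData, benjamini_hochberg,
                               censoring_km, concordance_index, cox_fit,
                               km_estimate, logrank_test, time_dependent_auc)


def _sd(time, event, ids=None):
    time = np.asarray(time, dtype=float)
    ids = ids if ids is not None else np.array([f"s{i}" for i in range(len(time))])
    return SurvivalData(ids, time, np.asarray(event))


class TestKaplanMeier:
    def test_all_events_closed_form(self):
        km = km_estimate(_sd([1, 2, 3], [1, 1, 1]))
        assert np.allclose(km.survival, [2 / 3, 1 / 3, 0.0])

    def test_all_censored_flat_at_one(self):
        km = km_estimate(_sd([5, 10, 15], [0, 0, 0]))
        assert km.evaluate(20.0) == 1.0 and len(km.event_times) == 0

    def test_censored_first_hand_oracle(self):
        # (1+, 2, 3): at t=2 risk set {2,3} -> S=1/2; at t=3 risk {3} -> S=0
        km = km_estimate(_sd([1, 2, 3], [0, 1, 1]))
        assert np.allclose(km.survival, [0.5, 0.0])

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(3, 40)
            km = km_estimate(_sd(rng.exponential(10, n) + 0.1, rng.integers(0, 2, n)))
            assert np.all(np.diff(km.survival) <= 1e-12)
            assert np.all((km.survival >= 0) & (km.survival <= 1))

    def test_matches_lifelines(self, exp_surv_data):
        lifelines = pytest.importorskip("lifelines")
        _, sd = exp_surv_data
        km = km_estimate(sd)
        kmf = lifelines.KaplanMeierFitter().fit(sd.time, sd.event)
        ref = kmf.survival_function_.loc[km.event_times, "KM_estimate"].to_numpy()
        assert np.allclose(km.survival, ref, atol=1e-12)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            _sd([0.0, 1.0], [1, 1])


class TestLogrank:
    def test_identical_groups_null(self):
        a = _sd([1, 2, 3, 4], [1, 0, 1, 1], ids=np.array(list("abcd")))
        b = _sd([1, 2, 3, 4], [1, 0, 1, 1], ids=np.array(list("wxyz")))
        chi2, p = logrank_test(a, b)
        assert chi2 == 0.0 and p == 1.0

    def test_hand_computed_six_sample_oracle(self):
        # group A: (1 ev, 3 ev, 5 cens); group B: (2 ev, 4 ev, 6 ev)
        a = _sd([1, 3, 5], [1, 1, 0], ids=np.array(list("abc")))
        b = _sd([2, 4, 6], [1, 1, 1], ids=np.array(list("xyz")))
        # observed-minus-expected tabulation by hand over event times 1,2,3,4,6:
        # t=1: nA=3,n=6,d=1,dA=1 -> O-E = 1-1/2,   V = (3/6)(3/6)(5/5)=0.25
        # t=2: nA=2,n=5,d=1,dA=0 -> O-E = -2/5,    V = (2/5)(3/5) = 0.24
        # t=3: nA=2,n=4,d=1,dA=1 -> O-E = 1/2,     V = 0.25
        # t=4: nA=1,n=3,d=1,dA=0 -> O-E = -1/3,    V = (1/3)(2/3) = 2/9
        # t=6: nA=0,n=1,d=1,dA=0 -> O-E = 0,       V = 0
        ome = 0.5 - 0.4 + 0.5 - 1 / 3 + 0.0
        var = 0.25 + 0.24 + 0.25 + 2 / 9
        chi2, p = logrank_test(a, b)
        assert chi2 == pytest.approx(ome**2 / var, abs=1e-12)
        assert p == pytest.approx(stats.chi2.sf(ome**2 / var, 1), abs=1e-12)

    def test_label_swap_symmetry(self, exp_surv_data):
        x, sd = exp_surv_data
        g = x > 0
        a = _sd(sd.time[g], sd.event[g], sd.sample_ids[g])
        b = _sd(sd.time[~g], sd.event[~g], sd.sample_ids[~g])
        assert logrank_test(a, b)[0] == pytest.approx(logrank_test(b, a)[0], abs=1e-12)

    def test_null_type_one_error_calibrated(self):
        """Equal exponential rates: rejection at 0.05 stays within binomial CI."""
        rng = np.random.default_rng(42)
        n_rep, rejections = 400, 0
        for _ in range(n_rep):
            ta = rng.exponential(10, 60)
            tb = rng.exponential(10, 60)
            a = _sd(ta, np.ones(60), np.array([f"a{i}" for i in range(60)]))
            b = _sd(tb, np.ones(60), np.array([f"b{i}" for i in range(60)]))
            rejections += logrank_test(a, b)[1] < 0.05
        lo, hi = stats.binom.interval(0.99, n_rep, 0.05)
        assert lo <= rejections <= hi

    def test_zero_events_rejected(self):
        a = _sd([1, 2], [0, 0], np.array(["a", "b"]))
        b = _sd([3, 4], [0, 0], np.array(["c", "d"]))
        with pytest.raises(ValueError):
            logrank_test(a, b)


class TestCox:
    def test_matches_lifelines(self, exp_surv_data):
        lifelines = pytest.importorskip("lifelines")
        x, sd = exp_surv_data
        fit = cox_fit(x[:, None], sd)
        df = pd.DataFrame({"t": sd.time, "e": sd.event, "x": x})
        cph = lifelines.CoxPHFitter().fit(df, "t", "e")
        assert fit.betas[0] == pytest.approx(cph.params_.iloc[0], abs=1e-4)
        assert fit.se[0] == pytest.approx(cph.standard_errors_.iloc[0], abs=1e-4)
        assert fit.hr[0] == pytest.approx(np.exp(fit.betas[0]), abs=0)

    def test_breslow_equals_efron_without_ties(self, exp_surv_data):
        x, sd = exp_surv_data
        assert len(np.unique(sd.time[sd.event == 1])) == sd.n_events
        fe = cox_fit(x[:, None], sd, ties="efron")
        fb = cox_fit(x[:, None], sd, ties="breslow")
        assert np.abs(fe.betas - fb.betas).max() < 1e-6

    def test_parameter_recovery(self):
        """Median estimate over 20 seeds within +-0.12 of true beta=0.7, n=500."""
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=500)
            t = rng.exponential(1.0 / (0.001 * np.exp(0.7 * x)))
            c = rng.exponential(1500.0, 500)
            sd = _sd(np.maximum(np.minimum(t, c), 0.01), (t <= c).astype(int))
            errs.append(cox_fit(x[:, None], sd).betas[0] - 0.7)
        assert abs(np.median(errs)) < 0.12

    def test_null_covariate_beta_near_zero(self):
        inside = 0
        for seed in range(60):
            rng = np.random.default_rng(1000 + seed)
            x = rng.normal(size=300)
            t = rng.exponential(1000.0, 300)
            sd = _sd(t, np.ones(300, dtype=int))
            fit = cox_fit(x[:, None], sd)
            inside += abs(fit.betas[0]) < 3 * fit.se[0]
        assert inside >= 0.95 * 60 - 3  # binomial slack on 60 draws

    def test_duplicated_column_collinearity_error(self, exp_surv_data):
        x, sd = exp_surv_data
        with pytest.raises(ValueError, match="rank deficient"):
            cox_fit(np.column_stack([x, x]), sd)

    def test_perfect_separation_flagged(self):
        # covariate = -time with all events: monotone likelihood
        t = np.arange(1.0, 31.0)
        sd = _sd(t, np.ones(30, dtype=int))
        with pytest.raises(ConvergenceError):
            cox_fit(-t[:, None], sd)

    def test_tied_times_efron_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(3)
        t = rng.integers(1, 15, 80).astype(float)  # heavy ties
        e = rng.integers(0, 2, 80)
        e[:2] = 1
        x = rng.normal(size=80)
        sd = _sd(t, e)
        fit = cox_fit(x[:, None], sd)
        df = pd.DataFrame({"t": t, "e": e, "x": x})
        cph = lifelines.CoxPHFitter().fit(df, "t", "e")
        assert fit.betas[0] == pytest.approx(cph.params_.iloc[0], abs=1e-4)


class TestConcordance:
    def test_perfect_ordering(self):
        t = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        sd = _sd(t, np.ones(5, dtype=int))
        assert concordance_index(-t, sd) == 1.0

    def test_null_risk_near_half(self):
        rng = np.random.default_rng(8)
        t = rng.exponential(10, 500) + 0.1
        sd = _sd(t, rng.integers(0, 2, 500))
        c = concordance_index(rng.normal(size=500), sd)
        assert 0.45 < c < 0.55

    def test_matches_sksurv_on_random_datasets(self):
        sksurv_metrics = pytest.importorskip("sksurv.metrics")
        rng = np.random.default_rng(9)
        for _ in range(50):
            n = int(rng.integers(10, 60))
            t = rng.integers(1, 20, n).astype(float)
            e = rng.integers(0, 2, n)
            if e.sum() == 0:
                e[0] = 1
            r = rng.normal(size=n).round(1)  # rounded -> risk ties exercised
            sd = _sd(t, e)
            ref = sksurv_metrics.concordance_index_censored(e.astype(bool), t, r)[0]
            assert concordance_index(r, sd) == pytest.approx(ref, abs=1e-12)

    def test_monotone_transform_invariance(self, exp_surv_data):
        x, sd = exp_surv_data
        assert concordance_index(x, sd) == concordance_index(np.exp(3 * x), sd)


class TestTimeDependentAUC:
    def test_no_censoring_equals_binary_auc(self):
        rng = np.random.default_rng(10)
        t = rng.exponential(10, 300) + 0.1
        risk = -t + rng.normal(0, 2, 300)
        sd = _sd(t, np.ones(300, dtype=int))
        horizon = float(np.median(t))
        label = t <= horizon
        auc = time_dependent_auc(risk, sd, horizon)
        ref = stats.mannwhitneyu(risk[label], risk[~label]).statistic / (
            label.sum() * (~label).sum())
        assert auc == pytest.approx(ref, abs=1e-12)

    def test_perfect_indicator_risk(self):
        t = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        sd = _sd(t, np.array([1, 1, 1, 0, 0, 0]))
        risk = (t <= 5).astype(float)
        assert time_dependent_auc(risk, sd, 5.0) == 1.0

    def test_matches_sksurv_ipcw_estimator(self, exp_surv_data):
        sksurv_metrics = pytest.importorskip("sksurv.metrics")
        from sksurv.util import Surv
        x, sd = exp_surv_data
        y = Surv.from_arrays(sd.event.astype(bool), sd.time)
        for horizon in (500.0, 1000.0):
            ref = sksurv_metrics.cumulative_dynamic_auc(y, y, x, [horizon])[0][0]
            assert time_dependent_auc(x, sd, horizon) == pytest.approx(ref, abs=1e-10)

    def test_binormal_analytic_value(self):
        """Risk and event-by-horizon from a binormal model: AUC = Phi(delta/sqrt(2))."""
        rng = np.random.default_rng(11)
        n, delta = 4000, 1.2
        label = rng.random(n) < 0.4
        risk = rng.normal(np.where(label, delta, 0.0), 1.0)
        t = np.where(label, rng.uniform(1, 9, n), rng.uniform(11, 20, n))
        sd = _sd(t, np.ones(n, dtype=int))
        auc = time_dependent_auc(risk, sd, 10.0)
        assert auc == pytest.approx(stats.norm.cdf(delta / np.sqrt(2)), abs=0.03)

    def test_no_cases_error(self):
        sd = _sd([10.0, 11.0], [1, 1], np.array(["a", "b"]))
        with pytest.raises(ValueError):
            time_dependent_auc(np.array([1.0, 2.0]), sd, 5.0)


class TestBenjaminiHochberg:
    def test_matches_step_up_oracle(self):
        p = np.array([0.01, 0.02, 0.04])
        assert np.allclose(benjamini_hochberg(p), [0.03, 0.03, 0.04])

    def test_matches_statsmodels_and_order_invariant(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(12)
        p = rng.random(200)
        ref = sm.multipletests(p, method="fdr_bh")[1]
        mine = benjamini_hochberg(p)
        assert np.allclose(mine, ref, atol=1e-12)
        perm = rng.permutation(200)
        assert np.allclose(benjamini_hochberg(p[perm]), mine[perm], atol=1e-12)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(13)
        p = rng.random(50) ** 2
        assert np.all(benjamini_hochberg(p) >= p - 1e-15)
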