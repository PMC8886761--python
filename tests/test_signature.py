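"""Signature builder: Cox gene screen, RF importance, K-means grouping,
PC1 scores against an eigendecomposition oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tmescore.signature import (GeneSignatureSet, RFConfig, cluster_genes,
                                compute_signature_scores, cox_screen_genes,
                                rank_importance, select_cumulative)
from tmescore.survival import SurvivalData
from tests.conftest import make_expression


def _surv(time, event, ids):
    return SurvivalData(np.asarray(ids), np.asarray(time, float), np.asarray(event))


class TestCoxScreenGenes:
    def test_null_gene_retained_at_nominal_rate(self):
        hits, n_rep = 0, 200
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            n = 150
            em = make_expression(rng.lognormal(3, 1, (1, n)))
            surv = _surv(rng.exponential(100, n) + 1, np.ones(n, int),
                         [f"s{i}" for i in range(n)])
            hits += len(cox_screen_genes(em, surv)) > 0
        lo, hi = stats.binom.interval(0.999, n_rep, 0.05)
        assert lo <= hits <= hi

    def test_planted_hazardous_gene_power(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 300
            x = rng.normal(size=n)
            t = rng.exponential(1.0 / (0.01 * np.exp(1.0 * x)))
            em = make_expression(np.exp(x)[None, :])  # lognormal expression, log = x
            surv = _surv(np.maximum(t, 0.1), np.ones(n, int),
                         [f"s{i}" for i in range(n)])
            hits += len(cox_screen_genes(em, surv)) > 0
        assert hits >= 19

    def test_zero_events_rejected(self):
        rng = np.random.default_rng(0)
        em = make_expression(rng.lognormal(3, 1, (2, 10)))
        surv = _surv(np.arange(1.0, 11.0), np.zeros(10, int),
                     [f"s{i}" for i in range(10)])
        with pytest.raises(ValueError):
            cox_screen_genes(em, surv)


class TestRankImportance:
    def test_perfectly_separating_gene_ranked_first(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 60
            y = np.repeat([0, 1], n // 2)
            vals = rng.lognormal(2, 0.5, (100, n))
            vals[0] = np.where(y == 1, 100.0, 1.0) * rng.lognormal(0, 0.05, n)
            em = make_expression(vals)
            cfg = RFConfig(mtry_min=1, mtry_max=5, ntree_search=50,
                           ntree_final=50, seed=seed)
            ranking = rank_importance(em, y, cfg)
            assert ranking.index[0] == "g0"

    def test_all_noise_importance_flat(self):
        rng = np.random.default_rng(3)
        n, g = 80, 40
        y = rng.integers(0, 2, n)
        em = make_expression(rng.lognormal(2, 0.5, (g, n)))
        cfg = RFConfig(mtry_min=3, mtry_max=3, ntree_search=50, ntree_final=200,
                       seed=0)
        ranking = rank_importance(em, y, cfg)
        # cumulative curve approximately linear: slope of the middle section
        cum = ranking["cumulative_fraction"].to_numpy()
        slope = np.diff(cum).mean()
        assert abs(slope - 1 / g) < 0.3 / g + 0.02

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 40)
        em = make_expression(rng.lognormal(2, 0.5, (20, 40)))
        cfg = RFConfig(mtry_min=1, mtry_max=3, ntree_search=30, ntree_final=30, seed=7)
        r1 = rank_importance(em, y, cfg)
        r2 = rank_importance(em, y, cfg)
        pd.testing.assert_frame_equal(r1, r2)

    def test_single_class_rejected(self):
        em = make_expression(np.ones((5, 20)))
        with pytest.raises(ValueError, match="single class"):
            rank_importance(em, np.zeros(20, int), RFConfig())


class TestSelectCumulative:
    def test_prefix_arithmetic(self):
        ranking = pd.DataFrame({
            "importance": [0.6, 0.35, 0.05],
            "cumulative_fraction": [0.6, 0.95, 1.0],
        }, index=["a", "b", "c"])
        assert select_cumulative(ranking, 0.95) == ["a", "b"]
        assert select_cumulative(ranking, 1.0) == ["a", "b", "c"]

    def test_single_gene(self):
        ranking = pd.DataFrame({"importance": [1.0], "cumulative_fraction": [1.0]},
                               index=["only"])
        for frac in (0.1, 0.95, 1.0):
            assert select_cumulative(ranking, frac) == ["only"]


class TestClusterGenes:
    def test_orthogonal_profiles_exact_partition(self):
        rng = np.random.default_rng(5)
        n = 40
        base_a = np.sin(np.linspace(0, 3 * np.pi, n))
        base_b = np.cos(np.linspace(0, 3 * np.pi, n))
        vals = np.vstack([5 + base_a + rng.normal(0, 0.01, n) for _ in range(6)]
                         + [5 + base_b + rng.normal(0, 0.01, n) for _ in range(6)])
        em = make_expression(vals)
        groups = cluster_genes(em, k=2, seed=0)
        sets = [set(g) for g in groups.values()]
        assert {frozenset(s) for s in sets} == {
            frozenset(f"g{i}" for i in range(6)),
            frozenset(f"g{i}" for i in range(6, 12))}

    def test_k_equals_n_genes_singletons(self):
        rng = np.random.default_rng(6)
        em = make_expression(rng.lognormal(2, 1, (4, 10)))
        groups = cluster_genes(em, k=4, seed=0)
        assert sorted(len(g) for g in groups.values()) == [1, 1, 1, 1]

    def test_group_names_ordered_by_mean_expression(self):
        rng = np.random.default_rng(7)
        lo = rng.uniform(1, 2, (3, 20))
        hi = rng.uniform(100, 200, (3, 20))
        em = make_expression(np.vstack([lo, hi]))
        groups = cluster_genes(em, k=2, seed=0)
        mean_g1 = em.data.loc[groups["G1"]].to_numpy().mean()
        mean_g2 = em.data.loc[groups["G2"]].to_numpy().mean()
        assert mean_g1 > mean_g2


class TestComputeSignatureScores:
    def test_single_gene_group_is_centered_expression(self):
        rng = np.random.default_rng(8)
        em = make_expression(rng.lognormal(2, 1, (1, 15)))
        sig = GeneSignatureSet({"G1": ["g0"]})
        with pytest.warns(UserWarning, match="< 2 genes"):
            scores = compute_signature_scores(em, sig)
        expected = em.data.loc["g0"] - em.data.loc["g0"].mean()
        assert np.allclose(scores["G1"].to_numpy(), expected.to_numpy())

    def test_two_gene_hand_arithmetic(self):
        # loadings (0.6, 0.8), centered expressions (1, 2) -> S = 2.2
        loading = np.array([0.6, 0.8])
        assert loading @ np.array([1.0, 2.0]) == pytest.approx(2.2)

    def test_loadings_match_eigendecomposition_oracle(self):
        rng = np.random.default_rng(9)
        vals = rng.lognormal(3, 0.8, (6, 50))
        em = make_expression(vals)
        sig = GeneSignatureSet({"G1": [f"g{i}" for i in range(6)]})
        scores = compute_signature_scores(em, sig)
        # brute-force oracle: leading eigenvector of the gene covariance
        xc = vals - vals.mean(axis=1, keepdims=True)
        cov = xc @ xc.T / (50 - 1)
        evals, evecs = np.linalg.eig(cov)
        lead = np.real(evecs[:, np.argmax(np.real(evals))])
        fitted = sig.loadings["G1"].to_numpy()
        assert min(np.abs(fitted - lead).max(),
                   np.abs(fitted + lead).max()) < 1e-8
        assert np.allclose(scores["G1"].to_numpy(), fitted @ xc, atol=1e-10)

    def test_pc1_variance_dominates_random_directions(self):
        rng = np.random.default_rng(10)
        vals = rng.lognormal(3, 0.8, (8, 60))
        em = make_expression(vals)
        sig = GeneSignatureSet({"G1": [f"g{i}" for i in range(8)]})
        scores = compute_signature_scores(em, sig)
        xc = vals - vals.mean(axis=1, keepdims=True)
        var_pc1 = scores["G1"].var()
        for _ in range(100):
            u = rng.normal(size=8)
            u /= np.linalg.norm(u)
            assert var_pc1 >= np.var(u @ xc, ddof=1) - 1e-10

    def test_unit_norm_loading_contract(self):
        rng = np.random.default_rng(11)
        em = make_expression(rng.lognormal(3, 1, (5, 30)))
        sig = GeneSignatureSet({"G1": [f"g{i}" for i in range(5)]})
        compute_signature_scores(em, sig)
        assert np.linalg.norm(sig.loadings["G1"]) == pytest.approx(1.0, abs=1e-12)

    def test_disjointness_enforced(self):
        with pytest.raises(ValueError, match="disjoint"):
            GeneSignatureSet({"G1": ["a", "b"], "G2": ["b", "c"]})
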