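"""Pagel's lambda likelihood machinery and independent contrasts."""

import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import star_tree
from sporetrade.phylo_signal import (
    fit_pagel_lambda,
    lambda_covariance,
    lambda_max_from_covariance,
    lambda_transform,
    pic_contrasts,
    pic_correlation,
    tree_covariance,
)
from sporetrade.synthetic_data import SimulationConfig, simulate_bm_trait, simulate_tree


class TestLambdaTransform:
    def test_identity_at_one(self, balanced_tree):
        C0, _ = tree_covariance(balanced_tree)
        C1, _ = tree_covariance(lambda_transform(balanced_tree, 1.0))
        assert np.allclose(C0, C1)

    def test_star_at_zero(self, balanced_tree):
        C, _ = tree_covariance(lambda_transform(balanced_tree, 0.0))
        off = C - np.diag(np.diag(C))
        assert np.allclose(off, 0.0)
        assert np.allclose(np.diag(C), 2.0)  # tip depths preserved

    def test_half_scales_off_diagonal_exactly(self, balanced_tree):
        C0, _ = tree_covariance(balanced_tree)
        C5, _ = tree_covariance(lambda_transform(balanced_tree, 0.5))
        assert np.allclose(np.diag(C5), np.diag(C0))
        off0 = C0 - np.diag(np.diag(C0))
        off5 = C5 - np.diag(np.diag(C5))
        assert np.allclose(off5, 0.5 * off0)

    def test_out_of_range_rejected(self, balanced_tree):
        C, _ = tree_covariance(balanced_tree)
        lmax = lambda_max_from_covariance(C)
        with pytest.raises(ValueError):
            lambda_transform(balanced_tree, lmax * 1.01)
        with pytest.raises(ValueError):
            lambda_transform(balanced_tree, -0.1)


class TestLambdaFit:
    def test_star_tree_likelihood_equals_iid_normal(self):
        """With no shared history the BM model collapses to iid normal."""
        tree = star_tree(12, length=2.0)
        rng = np.random.default_rng(5)
        x = pd.Series(rng.normal(3.0, 1.5, 12),
                      index=[f"t{i}" for i in range(12)])
        res = fit_pagel_lambda(tree, x, method="ml_mixture")
        v = x.to_numpy()
        sigma2_ml = np.var(v) * 1.0  # ML variance of the trait
        expected = np.sum(stats.norm.logpdf(v, v.mean(), np.sqrt(sigma2_ml)))
        assert res.logL_at_zero == pytest.approx(expected, abs=1e-8)

    def test_profile_matches_dense_grid_oracle(self):
        cfg = SimulationConfig(seed=42, n_species=60, lambda_true=0.7)
        tree = simulate_tree(cfg)
        trait = simulate_bm_trait(tree, cfg)
        for method in ("ml_mixture", "reml_mixture"):
            res = fit_pagel_lambda(tree, trait, method=method)
            from sporetrade.phylo_signal import _gls_profile_loglik
            C, labels = tree_covariance(tree)
            x = trait.reindex(labels).to_numpy()
            grid = np.linspace(0, res.lambda_max * (1 - 1e-10), 2001)
            best = max(_gls_profile_loglik(C, x, g, method == "reml_mixture")[0]
                       for g in grid)
            assert res.logL_at_hat >= best - 1e-6

    def test_recovers_strong_signal(self):
        cfg = SimulationConfig(seed=11, n_species=200, lambda_true=1.0)
        tree = simulate_tree(cfg)
        res = fit_pagel_lambda(tree, simulate_bm_trait(tree, cfg))
        assert 0.85 <= res.lambda_hat <= 1.05
        assert res.p_value < 1e-3

    def test_near_zero_for_iid_trait(self):
        cfg = SimulationConfig(seed=12, n_species=200, lambda_true=0.0)
        tree = simulate_tree(cfg)
        res = fit_pagel_lambda(tree, simulate_bm_trait(tree, cfg))
        assert res.lambda_hat < 0.15

    def test_lambda_invariant_to_affine_trait_change(self):
        cfg = SimulationConfig(seed=13, n_species=50, lambda_true=0.6)
        tree = simulate_tree(cfg)
        trait = simulate_bm_trait(tree, cfg)
        a = fit_pagel_lambda(tree, trait)
        b = fit_pagel_lambda(tree, 3.0 * trait + 10.0)
        assert a.lambda_hat == pytest.approx(b.lambda_hat, abs=1e-6)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-4)

    def test_lrt_fields_consistent(self):
        cfg = SimulationConfig(seed=14, n_species=40)
        tree = simulate_tree(cfg)
        res = fit_pagel_lambda(tree, simulate_bm_trait(tree, cfg))
        assert res.logL_at_hat >= res.logL_at_zero
        assert res.lrt_statistic == pytest.approx(
            2 * (res.logL_at_hat - res.logL_at_zero))
        assert 0 <= res.p_value <= 1

    def test_constant_trait_rejected(self, balanced_tree):
        x = pd.Series(1.0, index=list("abcd"))
        with pytest.raises(ValueError, match="zero variance"):
            fit_pagel_lambda(balanced_tree, x)

    def test_unmatched_tips_listed(self, balanced_tree):
        x = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "zz"])
        with pytest.raises(ValueError, match="zz"):
            fit_pagel_lambda(balanced_tree, x)


class TestContrasts:
    def test_two_tip_contrast_formula(self):
        tree = dendropy.Tree.get(data="(a:1,b:1);", schema="newick")
        cs = pic_contrasts(tree, {"a": 3.0, "b": 1.0})
        assert len(cs) == 1
        assert abs(cs.contrasts[0]) == pytest.approx(2 / np.sqrt(2))

    def test_constant_trait_gives_zero_contrasts(self, balanced_tree):
        cs = pic_contrasts(balanced_tree, dict.fromkeys("abcd", 5.0))
        assert np.allclose(cs.contrasts, 0.0)

    def test_contrast_count_is_tips_minus_one(self):
        cfg = SimulationConfig(seed=3, n_species=16)
        tree = simulate_tree(cfg)
        cs = pic_contrasts(tree, simulate_bm_trait(tree, cfg))
        assert len(cs) == 15
        assert np.all(cs.variances > 0)

    def test_polytomy_resolved_with_count(self):
        tree = star_tree(5)
        cs = pic_contrasts(tree, {f"t{i}": float(i) for i in range(5)})
        assert len(cs) == 4
        assert cs.n_polytomies_resolved == 1

    def test_negative_branch_rejected(self):
        tree = dendropy.Tree.get(data="(a:-1,b:1);", schema="newick")
        with pytest.raises(ValueError, match="negative"):
            pic_contrasts(tree, {"a": 1.0, "b": 2.0})

    def test_bm_contrasts_standardize_to_rate(self):
        """Standardized contrasts under BM have variance sigma^2."""
        cfg = SimulationConfig(seed=21, n_species=30, sigma2=2.5)
        tree = simulate_tree(cfg)
        allc = []
        for rep in range(100):
            trait = simulate_bm_trait(
                tree, cfg, rng=np.random.default_rng((21, rep)))
            allc.append(pic_contrasts(tree, trait).contrasts)
        var = np.var(np.concatenate(allc))
        assert var == pytest.approx(cfg.sigma2, rel=0.1)


class TestPicCorrelation:
    def test_trait_with_itself(self, balanced_tree):
        x = {"a": 1.0, "b": 4.0, "c": 2.0, "d": 9.0}
        res = pic_correlation(balanced_tree, x, x)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(0.0, abs=1e-12)

    def test_exact_doubling(self, balanced_tree):
        x = {"a": 1.0, "b": 4.0, "c": 2.0, "d": 9.0}
        y = {k: 2 * v for k, v in x.items()}
        res = pic_correlation(balanced_tree, x, y)
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)

    def test_type_one_error_under_independence(self):
        """Independent BM traits: contrast correlation rejects at ~alpha."""
        cfg = SimulationConfig(seed=31, n_species=100)
        tree = simulate_tree(cfg)
        rej = 0
        n_rep = 200
        for rep in range(n_rep):
            x = simulate_bm_trait(tree, cfg, rng=np.random.default_rng((31, rep, 0)))
            y = simulate_bm_trait(tree, cfg, rng=np.random.default_rng((31, rep, 1)))
            rej += pic_correlation(tree, x, y).p_value < 0.05
        lo, hi = stats.binom.interval(0.95, n_rep, 0.05)
        assert lo <= rej <= hi
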