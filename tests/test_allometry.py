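"""SMA regression, slope tests, and the trade-off / scaling analyses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from sporetrade.allometry import (
    ols_fit,
    scaling_analysis,
    sma_fit,
    test_sma_slope,
    tradeoff_analysis,
)
from sporetrade.biomass import build_allocation_table
from sporetrade.synthetic_data import SimulationConfig, simulate_allocation_experiment


def sma_loss(params, x, y):
    """Summed triangle areas between points and the line (SMA objective)."""
    a, b = params
    if b == 0:
        return np.inf
    resid = y - a - b * x
    return np.sum(resid**2) / abs(b)


def brute_force_sma(x, y):
    """Numerical minimizer of the SMA loss, independent of the closed form."""
    best = None
    ols = np.polyfit(x, y, 1)
    for b0 in (ols[0] + 0.5, ols[0] - 0.5, 1.0, -1.0):
        res = optimize.minimize(sma_loss, [ols[1], b0], args=(x, y),
                                method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    return best.x[1], best.x[0]


class TestSmaFit:
    def test_perfect_line(self):
        x = np.array([1.0, 2.0, 3.0])
        fit = sma_fit(x, 2 * x)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(0.0)
        assert fit.pearson_r == pytest.approx(1.0)

    def test_negative_slope_is_minus_sd_ratio(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([6.0, 5.0, 1.0])
        fit = sma_fit(x, y)
        assert fit.slope == pytest.approx(-np.sqrt(7.0))  # -sd(y)/sd(x)
        b, a = brute_force_sma(x, y)
        assert fit.slope == pytest.approx(b, abs=1e-4)
        assert fit.intercept == pytest.approx(a, abs=1e-4)

    def test_swap_gives_reciprocal_slope(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        y = 1.7 * x + rng.normal(scale=0.5, size=30)
        assert sma_fit(x, y).slope == pytest.approx(1 / sma_fit(y, x).slope)

    def test_ci_brackets_slope(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        y = -2.0 * x + rng.normal(scale=0.5, size=50)
        fit = sma_fit(x, y)
        assert fit.slope_ci[0] <= fit.slope <= fit.slope_ci[1]

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            sma_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            sma_fit([1.0, 2.0], [1.0, 2.0])

    @given(shift=st.floats(-100, 100), scale=st.floats(0.01, 100))
    @settings(max_examples=40, deadline=None)
    def test_slope_invariances(self, shift, scale):
        rng = np.random.default_rng(9)
        x = rng.normal(size=20)
        y = 0.8 * x + rng.normal(scale=0.3, size=20)
        base = sma_fit(x, y)
        shifted = sma_fit(x + shift, y + shift)
        assert shifted.slope == pytest.approx(base.slope, rel=1e-9)
        rescaled = sma_fit(scale * x, y)
        assert rescaled.slope == pytest.approx(base.slope / scale, rel=1e-9)


class TestOls:
    def test_perfect_line(self):
        x = np.array([1.0, 2.0, 3.0])
        assert ols_fit(x, 2 * x).slope == pytest.approx(2.0)

    def test_attenuation_identity_exact(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=40)
        y = -1.2 * x + rng.normal(scale=0.8, size=40)
        sma = sma_fit(x, y)
        ols = ols_fit(x, y)
        assert abs(ols.slope) == pytest.approx(
            abs(sma.pearson_r) * abs(sma.slope), rel=1e-12)
        assert abs(ols.slope) < abs(sma.slope)

    def test_uncorrelated_data_contrast(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=500)
        y = rng.normal(size=500) * 3.0
        assert abs(ols_fit(x, y).slope) < 0.3
        assert abs(sma_fit(x, y).slope) == pytest.approx(
            np.std(y, ddof=1) / np.std(x, ddof=1))


class TestSlopeTest:
    def test_self_hypothesis_p_is_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        fit = sma_fit(x, -1.5 * x + 4)
        assert test_sma_slope(fit, fit.slope) == pytest.approx(1.0)

    def test_zero_hypothesis_rejected(self):
        fit = sma_fit([1.0, 2.0, 3.0], [1.0, 2.5, 2.8])
        with pytest.raises(ValueError):
            test_sma_slope(fit, 0.0)

    def test_detects_wrong_slope_with_low_noise(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=50)
        y = -0.5 * x + rng.normal(scale=0.05, size=50)
        fit = sma_fit(x, y)
        assert test_sma_slope(fit, -1.0) < 1e-6

    def test_power_against_minus_one_at_half(self):
        """True slope -0.5, n = 50: the b0 = -1 test should usually reject."""
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(200):
            x = rng.normal(size=50)
            y = -0.5 * x + rng.normal(scale=0.25, size=50)
            hits += test_sma_slope(sma_fit(x, y), -1.0) < 0.05
        assert hits / 200 > 0.8


def _noiseless_alloc(b_true, seed=3, logA_sd=0.0):
    cfg = SimulationConfig(seed=seed, b_true=b_true, logA_sd=logA_sd,
                           noise_cv=0.0, host_effect_sd=0.0)
    rec, truth = simulate_allocation_experiment(cfg)
    return build_allocation_table(rec, truth["W0_ug"])


class TestTradeoffAnalysis:
    def test_constant_budget_forces_inverse_proportionality(self):
        report = tradeoff_analysis(_noiseless_alloc(b_true=1.0))
        fit = report.variant_uncorrected
        assert fit.slope == pytest.approx(-1.0, abs=1e-12)
        assert fit.p_vs_hypothesis == pytest.approx(1.0)
        # constant A leaves no allocation-size line to fit
        assert report.allocation_vs_size is None

    def test_half_exponent_recovered_with_positive_allocation_slope(self):
        report = tradeoff_analysis(_noiseless_alloc(b_true=0.5))
        assert report.variant_uncorrected.slope == pytest.approx(-0.5, abs=1e-12)
        assert report.allocation_vs_size.slope == pytest.approx(0.5, abs=1e-12)

    def test_shared_spore_size_rejected(self):
        alloc = _noiseless_alloc(b_true=1.0)
        alloc["spore_mass_W0"] = 0.5
        with pytest.raises(ValueError, match="variance"):
            tradeoff_analysis(alloc)

    @pytest.mark.parametrize("b_true", [0.1, 0.5, 1.0, 1.5, 2.0])
    def test_generator_exponent_recovered_noiselessly(self, b_true):
        report = tradeoff_analysis(_noiseless_alloc(b_true=b_true))
        assert -report.variant_uncorrected.slope == pytest.approx(b_true, rel=1e-9)

    def test_pic_check_attached_when_significant(self):
        from sporetrade.synthetic_data import simulate_tree
        cfg = SimulationConfig(seed=17, b_true=1.0, noise_cv=0.1,
                               host_effect_sd=0.0, w0_on_tree=True)
        tree = simulate_tree(cfg)
        rec, truth = simulate_allocation_experiment(cfg, tree=tree)
        alloc = build_allocation_table(rec, truth["W0_ug"])
        report = tradeoff_analysis(alloc, tree=tree)
        assert report.variant_uncorrected.p_correlation < 0.05
        assert "output_vs_size" in report.pic_checks
        assert report.pic_checks["output_vs_size"].r < 0


class TestScalingAnalysis:
    def test_isometric_output_scaling(self):
        """R proportional to Walpha with near-constant W0: beta-hat = 1."""
        rng = np.random.default_rng(8)
        walpha = 10 ** rng.normal(2, 0.5, 40)
        w0 = 10 ** rng.normal(-0.5, 0.01, 40)  # effectively flat
        alloc = pd.DataFrame({
            "fungal_species": [f"s{i}" for i in range(40)],
            "spore_output_R": 3.0 * walpha,
            "spore_mass_W0": w0,
            "body_mass_Walpha": walpha,
            "extraradical_length": walpha / 10,
            "allocation_A": 3.0 * walpha * w0,
        })
        report = scaling_analysis(alloc)
        assert report.beta_hat == pytest.approx(1.0, abs=0.05)
        assert report.output_vs_body.slope == pytest.approx(1.0, abs=1e-9)
        assert report.size_vs_body.p_correlation > 0.05

    def test_independent_size_null_rate(self):
        """W0 independent of Walpha: size-body significance near alpha."""
        from scipy import stats as sps
        rng = np.random.default_rng(10)
        rej = 0
        n_rep = 300
        for _ in range(n_rep):
            walpha = 10 ** rng.normal(2, 0.5, 30)
            w0 = 10 ** rng.normal(-0.5, 0.5, 30)
            r = 10 * walpha / w0
            alloc = pd.DataFrame({
                "fungal_species": [f"s{i}" for i in range(30)],
                "spore_output_R": r,
                "spore_mass_W0": w0,
                "body_mass_Walpha": walpha,
                "extraradical_length": walpha,
                "allocation_A": r * w0,
            })
            rej += scaling_analysis(alloc).size_vs_body.p_correlation < 0.05
        lo, hi = sps.binom.interval(0.95, n_rep, 0.05)
        assert lo <= rej <= hi

    def test_zero_variance_body_size_rejected(self):
        alloc = _noiseless_alloc(b_true=1.0)
        alloc["body_mass_Walpha"] = 42.0
        with pytest.raises(ValueError, match="variance"):
            scaling_analysis(alloc)
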