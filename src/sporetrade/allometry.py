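"""Offspring size-number trade-off and body-size scaling via SMA regression.

The Smith-Fretwell model says a parent with reproductive budget A making
offspring of size W0 produces ``R = A / W0^b`` of them; on logs this is a
line with slope ``-b``, and ``b = 1`` means exact inverse proportionality
(size and number trade off under a fixed budget).  The body-size scaling
hypothesis is ``R * W0 = sigma * Walpha^beta``.  Both variables in these
relationships carry sampling error, so the line of interest is the
standardized major axis (SMA): slope = sign(r) * sd(y)/sd(x), symmetric in
x and y.  Ordinary least squares is kept for the attenuation comparison
(|OLS slope| = |r| * |SMA slope|, so OLS always underestimates allometric
slopes when r is imperfect).

Slope inference follows Warton et al. (2006): the 95% CI comes from the
correlation-based F statistic, and a hypothesized slope b0 is tested via the
correlation between the rotated axes y - b0*x and y + b0*x, which is zero
exactly when the population SMA slope equals b0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from sporetrade.phylo_signal import PICCorrelation, pic_correlation

logger = logging.getLogger(__name__)


@dataclass
class SMAResult:
    slope: float
    intercept: float
    n: int
    pearson_r: float
    r_squared: float
    slope_ci: tuple[float, float]
    p_correlation: float
    hypothesized_slope: float | None = None
    p_vs_hypothesis: float | None = None
    x: np.ndarray = field(default=None, repr=False)
    y: np.ndarray = field(default=None, repr=False)

    def as_dict(self) -> dict:
        return {
            "slope": self.slope, "intercept": self.intercept, "n": self.n,
            "pearson_r": self.pearson_r, "r_squared": self.r_squared,
            "slope_ci_low": self.slope_ci[0], "slope_ci_high": self.slope_ci[1],
            "p_correlation": self.p_correlation,
            "hypothesized_slope": self.hypothesized_slope,
            "p_vs_hypothesis": self.p_vs_hypothesis,
        }


def _validate_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError(f"need at least 3 points, got {len(x)}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in x or y")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    return x, y


def sma_fit(x, y, *, alpha: float = 0.05) -> SMAResult:
    """Standardized major axis fit of y on x (both on log scale by convention).

    slope = sign(r) * sd(y)/sd(x); the CI uses
    ``B = F(1-alpha; 1, n-2) * (1 - r^2)/(n - 2)`` with limits
    ``slope * (sqrt(B + 1) +/- sqrt(B))``; p_correlation is the two-sided
    test of r = 0 (equivalently, of the SMA slope being estimable at all).
    """
    x, y = _validate_xy(x, y)
    n = len(x)
    r, p_corr = stats.pearsonr(x, y)
    r = float(r)
    sign = -1.0 if r < 0 else 1.0
    slope = sign * np.std(y, ddof=1) / np.std(x, ddof=1)
    intercept = float(np.mean(y) - slope * np.mean(x))

    B = stats.f.ppf(1.0 - alpha, 1, n - 2) * (1.0 - r * r) / (n - 2)
    ci = sorted((slope * (np.sqrt(B + 1.0) + np.sqrt(B)),
                 slope * (np.sqrt(B + 1.0) - np.sqrt(B))))
    return SMAResult(
        slope=float(slope), intercept=intercept, n=n, pearson_r=r,
        r_squared=r * r, slope_ci=(float(ci[0]), float(ci[1])),
        p_correlation=float(p_corr), x=x, y=y,
    )


def ols_fit(x, y):
    """Ordinary least squares of y on x (scipy linregress result).

    Kept only for the attenuation comparison with SMA; |OLS| = |r| * |SMA|.
    """
    x, y = _validate_xy(x, y)
    return stats.linregress(x, y)


def test_sma_slope(fit: SMAResult, b0: float) -> float:
    """Two-sided p for H0: SMA slope = b0 (e.g. -1, inverse proportionality).

    Tests zero correlation between the rotated axes ``y - b0 x`` (residual)
    and ``y + b0 x`` (fitted), with n - 2 degrees of freedom.  Updates the
    fit's ``hypothesized_slope``/``p_vs_hypothesis`` fields and returns p.
    """
    if b0 == 0:
        raise ValueError("b0 = 0 is undefined for an SMA slope test")
    if fit.x is None or fit.y is None:
        raise ValueError("fit does not retain its data; refit with sma_fit")
    u = fit.y - b0 * fit.x
    v = fit.y + b0 * fit.x
    n = fit.n
    # relative floor: rotated axes constant up to float rounding count as exact
    scale = max(np.std(fit.y), abs(b0) * np.std(fit.x))
    if np.std(u) <= 1e-9 * scale:
        p = 1.0  # data lie exactly on a line of slope b0
    elif np.std(v) <= 1e-9 * scale:
        p = 0.0  # data lie exactly on a line of slope -b0
    else:
        r = float(np.clip(stats.pearsonr(u, v)[0], -1.0, 1.0))
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = abs(r) * np.sqrt((n - 2) / (1.0 - r * r))
            p = float(2.0 * stats.t.sf(t, n - 2))
    fit.hypothesized_slope = float(b0)
    fit.p_vs_hypothesis = p
    return p


test_sma_slope.__test__ = False  # statistical test, not a pytest case


# ---------------------------------------------------------------------------
# the study-level analyses

@dataclass
class TradeoffReport:
    """SMA trade-off fits across the three body-size corrections.

    All variants use the same species x host points: (a) uncorrected
    log R ~ log W0; (b) output per meter of extraradical mycelium;
    (c) output per unit total mycelium mass; plus log A ~ log W0 for the
    allocation-size relationship.
    """

    variant_uncorrected: SMAResult
    variant_per_length: SMAResult
    variant_per_mass: SMAResult
    allocation_vs_size: SMAResult | None
    n_points: int
    pic_checks: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "n_points": self.n_points,
            "variant_uncorrected": self.variant_uncorrected.as_dict(),
            "variant_per_length": self.variant_per_length.as_dict(),
            "variant_per_mass": self.variant_per_mass.as_dict(),
            "allocation_vs_size": (self.allocation_vs_size.as_dict()
                                   if self.allocation_vs_size else None),
        }
        d["pic_checks"] = {k: v.as_dict() for k, v in self.pic_checks.items()}
        return d


@dataclass
class ScalingReport:
    """Scaling of spore size, output, and allocation with body size Walpha."""

    size_vs_body: SMAResult        # log W0 ~ log Walpha
    output_vs_body: SMAResult      # log R ~ log Walpha
    allocation_vs_body: SMAResult  # log(R W0) ~ log Walpha: slope = beta-hat
    n_points: int

    @property
    def beta_hat(self) -> float:
        return self.allocation_vs_body.slope

    @property
    def log10_sigma_hat(self) -> float:
        return self.allocation_vs_body.intercept

    def as_dict(self) -> dict:
        return {
            "n_points": self.n_points,
            "size_vs_body": self.size_vs_body.as_dict(),
            "output_vs_body": self.output_vs_body.as_dict(),
            "allocation_vs_body": self.allocation_vs_body.as_dict(),
            "beta_hat": self.beta_hat,
            "log10_sigma_hat": self.log10_sigma_hat,
        }


REQUIRED_ALLOCATION_COLUMNS = (
    "fungal_species", "spore_output_R", "spore_mass_W0",
    "body_mass_Walpha", "extraradical_length", "allocation_A",
)


def _clean_points(records: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    df = records.copy()
    ok = np.ones(len(df), dtype=bool)
    for c in cols:
        ok &= df[c].to_numpy(float) > 0
    if not ok.all():
        logger.info("excluding %d points with non-positive %s", (~ok).sum(), cols)
    df = df[ok]
    if len(df) < 3:
        raise ValueError("fewer than 3 usable species x host points")
    return df


def tradeoff_analysis(records: pd.DataFrame, *, tree=None, alpha: float = 0.05,
                      hypothesized_slope: float = -1.0) -> TradeoffReport:
    """Fit the offspring size-output trade-off in its three corrections.

    ``records`` is the allocation table from the biomass module (one row per
    species x host).  Each variant is an SMA fit on base-10 logs and is
    tested against the inverse-proportionality slope -1.  When the
    uncorrected correlation is significant at ``alpha`` and a tree covering
    the species is supplied, a phylogenetically independent contrast
    correlation (on per-species mean logs) is attached.
    """
    df = _clean_points(records, ["spore_output_R", "spore_mass_W0"])
    logW0 = np.log10(df["spore_mass_W0"].to_numpy(float))
    logR = np.log10(df["spore_output_R"].to_numpy(float))

    fit_a = sma_fit(logW0, logR, alpha=alpha)
    test_sma_slope(fit_a, hypothesized_slope)

    df_b = _clean_points(df, ["extraradical_length"])
    fit_b = sma_fit(
        np.log10(df_b["spore_mass_W0"].to_numpy(float)),
        np.log10(df_b["spore_output_R"].to_numpy(float)
                 / df_b["extraradical_length"].to_numpy(float)),
        alpha=alpha)
    test_sma_slope(fit_b, hypothesized_slope)

    df_c = _clean_points(df, ["body_mass_Walpha"])
    fit_c = sma_fit(
        np.log10(df_c["spore_mass_W0"].to_numpy(float)),
        np.log10(df_c["spore_output_R"].to_numpy(float)
                 / df_c["body_mass_Walpha"].to_numpy(float)),
        alpha=alpha)
    test_sma_slope(fit_c, hypothesized_slope)

    try:
        fit_A = sma_fit(logW0, np.log10(df["allocation_A"].to_numpy(float)),
                        alpha=alpha)
        test_sma_slope(fit_A, hypothesized_slope)
    except ValueError as exc:
        # constant allocation A (exact budget) has no SMA line against W0
        logger.info("allocation-size fit degenerate: %s", exc)
        fit_A = None

    pic_checks: dict[str, PICCorrelation] = {}
    if tree is not None and fit_a.p_correlation < alpha:
        means = (df.assign(logW0=logW0, logR=logR)
                   .groupby("fungal_species")[["logW0", "logR"]].mean())
        try:
            pic_checks["output_vs_size"] = pic_correlation(
                tree, means["logW0"], means["logR"])
        except ValueError as exc:
            logger.warning("PIC check skipped: %s", exc)

    return TradeoffReport(
        variant_uncorrected=fit_a, variant_per_length=fit_b,
        variant_per_mass=fit_c, allocation_vs_size=fit_A,
        n_points=len(df), pic_checks=pic_checks,
    )


def scaling_analysis(records: pd.DataFrame, *, alpha: float = 0.05) -> ScalingReport:
    """Fit reproductive traits against body size Walpha on base-10 logs.

    Reports log W0 ~ log Walpha and log R ~ log Walpha, plus
    log(R W0) ~ log Walpha whose slope is the scaling exponent beta-hat and
    intercept log10 of the proportionality constant.
    """
    df = _clean_points(
        records, ["spore_output_R", "spore_mass_W0", "body_mass_Walpha"])
    logW0 = np.log10(df["spore_mass_W0"].to_numpy(float))
    logR = np.log10(df["spore_output_R"].to_numpy(float))
    logWa = np.log10(df["body_mass_Walpha"].to_numpy(float))

    return ScalingReport(
        size_vs_body=sma_fit(logWa, logW0, alpha=alpha),
        output_vs_body=sma_fit(logWa, logR, alpha=alpha),
        allocation_vs_body=sma_fit(logWa, logR + logW0, alpha=alpha),
        n_points=len(df),
    )
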