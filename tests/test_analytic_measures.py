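"""Closed-form measures against Monte-Carlo / numerical oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from deltadisp.analytic_measures import (
    analytic_cv,
    analytic_entropy,
    analytic_gini,
    analytic_profile,
    analytic_skewness,
    bias_curve,
    quantile_range_95,
)
from deltadisp.distributions import BetaSpec, BoundsSpec, GammaSpec

BETA_GRID = [(p, q) for p in (0.5, 1, 2, 5) for q in (0.5, 1, 2, 5)]
GAMMA_GRID = [(k, d) for k in (0.5, 1, 2, 5) for d in (0.5, 1, 2)]


def _batch_se(per_batch):
    return np.std(per_batch, ddof=1) / math.sqrt(len(per_batch))


def _mc_stats(draws, logpdf, n_batches=50):
    """Monte-Carlo CV / Gini / entropy with batch-means standard errors."""
    batches = np.array_split(draws, n_batches)
    lp = np.array_split(logpdf, n_batches)
    cvs, ginis, ents = [], [], []
    for xb, lb in zip(batches, lp):
        mu = xb.mean()
        cvs.append(xb.std(ddof=1) / mu)
        half = xb.size // 2
        ginis.append(np.mean(np.abs(xb[:half] - xb[half:2 * half])) / (2 * mu))
        ents.append(-lb.mean())
    return (np.mean(cvs), _batch_se(cvs)), (np.mean(ginis), _batch_se(ginis)), \
           (np.mean(ents), _batch_se(ents))


@pytest.mark.parametrize("p,q", BETA_GRID)
def test_beta_measures_match_monte_carlo(p, q):
    """Analytic CV/Gini/entropy agree with 200k-draw MC within 3 SE."""
    rng = np.random.default_rng(hash((p, q)) % 2**31)
    x = rng.beta(p, q, size=200_000)
    (cv, cv_se), (g, g_se), (h, h_se) = _mc_stats(x, stats.beta.logpdf(x, p, q))
    spec = BetaSpec(p, q)
    assert abs(analytic_cv(spec) - cv) < 3 * cv_se + 1e-4
    assert abs(analytic_gini(spec) - g) < 3 * g_se + 1e-4
    assert abs(analytic_entropy(spec) - h) < 3 * h_se + 1e-3


@pytest.mark.parametrize("k,d", GAMMA_GRID)
def test_gamma_measures_match_monte_carlo(k, d):
    rng = np.random.default_rng(hash((k, d)) % 2**31)
    x = rng.gamma(k, scale=d, size=200_000)
    (cv, cv_se), (g, g_se), (h, h_se) = _mc_stats(x, stats.gamma.logpdf(x, k, scale=d))
    spec = GammaSpec(k, d)
    assert abs(analytic_cv(spec) - cv) < 3 * cv_se + 1e-3
    assert abs(analytic_gini(spec) - g) < 3 * g_se + 1e-3
    assert abs(analytic_entropy(spec) - h) < 3 * h_se + 1e-3


@pytest.mark.parametrize("spec,expected", [
    (GammaSpec(1, 1), 0.5),              # exponential Gini
    (GammaSpec(0.5, 1), 2 / math.pi),
    (BetaSpec(1, 1), 1 / 3),             # uniform Gini
])
def test_gini_special_values(spec, expected):
    assert analytic_gini(spec) == pytest.approx(expected, abs=1e-12)


def test_gini_overflow_safe_for_huge_shapes():
    g = analytic_gini(BetaSpec(5e4, 5e4))
    assert 0 < g < 0.01 and np.isfinite(g)
    assert np.isfinite(analytic_gini(GammaSpec(1e6, 1.0)))


@pytest.mark.parametrize("spec,expected", [
    (GammaSpec(1, 1), 1.0),                                  # Exp(1): 1 nat
    (BetaSpec(1, 1), 0.0),                                   # uniform on [0,1]
    (BetaSpec(1, 1, BoundsSpec(0, 100)), math.log(100)),     # scale adjustment
])
def test_entropy_special_values(spec, expected):
    assert analytic_entropy(spec) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("k,expected_cv", [(4, 0.5), (1, 1.0)])
def test_gamma_cv(k, expected_cv):
    assert analytic_cv(GammaSpec(k, 7.0)) == pytest.approx(expected_cv, abs=1e-12)


@pytest.mark.parametrize("p,q,expected", [
    (1, 1, math.sqrt(1 / 12) / 0.5),
    (1, 3, 0.7745966692414834),
])
def test_beta_cv(p, q, expected):
    assert analytic_cv(BetaSpec(p, q)) == pytest.approx(expected, rel=1e-12)


@settings(derandomize=True, max_examples=50)
@given(k=st.floats(0.01, 1e4))
def test_gamma_skewness_is_twice_cv(k):
    spec = GammaSpec(k, 1.0)
    assert analytic_skewness(spec) == 2.0 * analytic_cv(spec)


@pytest.mark.parametrize("spec,expected", [
    (BetaSpec(1, 1), 0.95),
    (GammaSpec(1, 1), -math.log(0.025) + math.log(0.975)),
])
def test_quantile_range_closed_forms(spec, expected):
    assert quantile_range_95(spec) == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize("p,q", BETA_GRID)
def test_beta_quantile_range_vs_bisection_oracle(p, q):
    from scipy.optimize import brentq

    lo = brentq(lambda x: stats.beta.cdf(x, p, q) - 0.025, 0, 1, xtol=1e-12)
    hi = brentq(lambda x: stats.beta.cdf(x, p, q) - 0.975, 0, 1, xtol=1e-12)
    assert quantile_range_95(BetaSpec(p, q)) == pytest.approx(hi - lo, abs=1e-9)


@pytest.mark.parametrize("k,d", GAMMA_GRID)
def test_gamma_quantile_range_vs_scipy(k, d):
    ref = stats.gamma.ppf(0.975, k, scale=d) - stats.gamma.ppf(0.025, k, scale=d)
    assert quantile_range_95(GammaSpec(k, d)) == pytest.approx(ref, abs=1e-8)


def test_quantile_range_shift_and_flip_invariant():
    base = quantile_range_95(GammaSpec(2, 1.5))
    assert quantile_range_95(GammaSpec(2, 1.5, BoundsSpec(lower=100.0))) == \
        pytest.approx(base, abs=1e-9)
    assert quantile_range_95(GammaSpec(2, 1.5, BoundsSpec(upper=100.0))) == \
        pytest.approx(base, abs=1e-9)


def test_profile_internal_consistency():
    prof = analytic_profile(GammaSpec(2, 3, BoundsSpec(lower=5.0)))
    assert prof.sd ** 2 == pytest.approx(prof.variance, abs=1e-12)
    assert prof.delta == 3.0
    prof_b = analytic_profile(BetaSpec(2, 2, BoundsSpec(0, 100)))
    assert prof_b.qrange95 <= 100.0
    assert prof_b.variance == pytest.approx(0.05 * 100 ** 2, abs=1e-9)


# --- bias curves: the mean-dependence shapes of each measure ---------------


def test_bias_curve_variance_linear_in_mean():
    df = bias_curve("variance", BoundsSpec(lower=0), 1.0, [1.0, 2.0, 4.0])
    np.testing.assert_allclose(df["value"], [1.0, 2.0, 4.0], atol=1e-12)


def test_bias_curve_sd_square_root():
    df = bias_curve("sd", BoundsSpec(lower=0), 1.0, [1.0, 2.0, 4.0])
    np.testing.assert_allclose(df["value"], np.sqrt([1.0, 2.0, 4.0]), atol=1e-12)


def test_bias_curve_delta_is_exactly_flat():
    df = bias_curve("delta", BoundsSpec(lower=0), 2.5, np.linspace(1, 500, 40))
    assert np.ptp(df["value"].to_numpy()) == 0.0
    df2 = bias_curve("delta", BoundsSpec(0, 100), 0.2, np.linspace(5, 95, 40))
    assert np.ptp(df2["value"].to_numpy()) == 0.0


def test_bias_curve_monotone_shapes():
    """At fixed dispersion: variance increasing & linear, sd concave
    increasing, CV decreasing (gamma); beta variance peaks at centre."""
    means = np.linspace(5, 500, 60)
    var = bias_curve("variance", BoundsSpec(lower=0), 2.0, means)["value"].to_numpy()
    sd = bias_curve("sd", BoundsSpec(lower=0), 2.0, means)["value"].to_numpy()
    cv = bias_curve("cv", BoundsSpec(lower=0), 2.0, means)["value"].to_numpy()
    assert np.all(np.diff(var) > 0)
    np.testing.assert_allclose(np.diff(var), np.diff(var)[0], rtol=1e-9)  # linear
    assert np.all(np.diff(sd) > 0) and np.all(np.diff(np.diff(sd)) < 0)  # concave
    assert np.all(np.diff(cv) < 0)

    means_b = np.linspace(5, 95, 91)
    var_b = bias_curve("variance", BoundsSpec(0, 100), 0.2, means_b)["value"].to_numpy()
    peak = means_b[np.argmax(var_b)]
    assert peak == pytest.approx(50.0, abs=1.0)
    np.testing.assert_allclose(var_b, var_b[::-1], atol=1e-9)  # symmetric


def test_bias_curve_undefined_points_become_nan():
    df = bias_curve("variance", BoundsSpec(0, 100), 0.2, [50.0, 150.0])
    assert np.isfinite(df["value"].iloc[0])
    assert np.isnan(df["value"].iloc[1])
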