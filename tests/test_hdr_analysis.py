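"""Warp-grid artifact mechanism and the richness model suite."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from deltadisp.distributions import BoundsSpec
from deltadisp.hdr_analysis import (
    CATALONIA_RICHNESS,
    MODEL_TERMS,
    RichnessModelSpec,
    border_cell_filter,
    fit_model_suite,
    fit_quadratic_hdr,
    make_warp_grid,
    nested_f_test,
    richness_truth,
)
from deltadisp.synthetic_data import gen_richness_survey


@pytest.mark.parametrize("mu,delta,expected,tol", [
    (0.0, 0.0, 66.395, 1e-12),
    (1000.0, 100.0, 95.615, 1e-9),
    (2422.0, 0.64, 70.2576, 1e-3),
])
def test_richness_truth_values(mu, delta, expected, tol):
    assert richness_truth(mu, delta) == pytest.approx(expected, abs=tol)


def test_richness_truth_optional_quadratic_delta():
    spec = RichnessModelSpec(1.0, 0.0, 0.0, 0.0, delta_quadratic=2.0)
    assert richness_truth(0.0, 3.0, spec) == 19.0


@pytest.fixture(scope="module")
def warp7():
    return make_warp_grid(n_per_axis=7)


@pytest.fixture(scope="module")
def warp_fit_grid():
    """The polynomial-fitting grid (fast 50x50 mode)."""
    return make_warp_grid(n_per_axis=50)


def test_warp_grid_shape_and_truth(warp7):
    assert len(warp7) == 49
    np.testing.assert_allclose(warp7["richness"],
                               richness_truth(warp7["mu"], warp7["delta"]))


def test_warp_grid_delta_constant_within_slice(warp7):
    for _, slc in warp7.groupby("delta"):
        assert slc["delta"].nunique() == 1
        # the observed range grows with the mean at fixed dispersion
        ordered = slc.sort_values("mu")["range"].to_numpy()
        assert np.all(np.diff(ordered) > 0)


def test_warp_grid_beta_family():
    grid = make_warp_grid(mu_range=(0.1, 0.9), delta_range=(0.05, 0.3),
                          n_per_axis=5, family="beta", bounds=BoundsSpec(0, 1))
    assert len(grid) == 25
    assert np.isfinite(grid[["sd", "cv", "gini", "entropy", "range"]]).all().all()


def test_fit_quadratic_recovers_exact_polynomial():
    rngx = np.linspace(0, 1, 30)
    records = pd.DataFrame({"m": rngx, "richness": 2.0 + 3.0 * rngx - 1.5 * rngx ** 2})
    fit = fit_quadratic_hdr(records, "m", rescale=False)
    assert fit.params["const"] == pytest.approx(2.0, abs=1e-8)
    assert fit.params["m"] == pytest.approx(3.0, abs=1e-8)
    assert fit.params["m2"] == pytest.approx(-1.5, abs=1e-8)


def test_spurious_hump_on_range_but_not_on_delta(warp_fit_grid):
    """The headline artifact: a purely linear dispersion effect plus a
    hump-shaped mean effect produces a hump-shaped quadratic in the
    range-based (also sd- and cv-based) observed heterogeneity, while
    the delta-based fit stays linear."""
    for measure in ("range", "sd", "cv"):
        fit = fit_quadratic_hdr(warp_fit_grid, measure)
        assert fit.params[f"{measure}2"] != pytest.approx(0.0, abs=1e-6)
    f_range = fit_quadratic_hdr(warp_fit_grid, "range")
    assert f_range.params["range2"] < 0
    f_delta = fit_quadratic_hdr(warp_fit_grid, "delta")
    assert abs(f_delta.params["delta2"]) <= 0.01 * abs(f_delta.params["delta"])
    assert f_delta.params["delta"] > 0


def test_model_suite_noise_free_model5_is_exact():
    cells = gen_richness_survey(noise_sd=0.0, seed=4)
    fits = fit_model_suite(cells)
    tags = [f.tag for f in fits]
    assert tags == ["#1", "#2", "#3", "#4", "#5"]
    m5 = fits[4]
    assert m5.adj_r2 == pytest.approx(1.0, abs=1e-10)
    assert set(m5.terms) == set(MODEL_TERMS[5])


def test_model_suite_duplicated_rows_leave_coefficients_unchanged():
    cells = gen_richness_survey(n_cells=60, noise_sd=2.0, seed=9)
    fits = fit_model_suite(cells, models=(5,))
    doubled = fit_model_suite(pd.concat([cells, cells], ignore_index=True), models=(5,))
    for term, coef in fits[0].params.items():
        assert doubled[0].params[term] == pytest.approx(coef, rel=1e-9)


def test_model_suite_recovers_coefficient_signs():
    cells = gen_richness_survey(n_cells=285, noise_sd=5.0, seed=11)
    m5 = fit_model_suite(cells, models=(5,))[0]
    assert m5.params["delta"] > 0
    assert m5.params["mu2"] < 0
    assert m5.pvalues["delta"] < 0.01


def test_model_suite_missing_columns_error():
    cells = gen_richness_survey(n_cells=30, seed=0).drop(columns=["rho"])
    with pytest.raises(ValueError, match="rho"):
        fit_model_suite(cells, models=(1,))
    fit_model_suite(cells, models=(5,))  # rho not needed for #5


def test_nested_f_identical_models():
    cells = gen_richness_survey(n_cells=50, noise_sd=1.0, seed=2)
    fit = fit_model_suite(cells, models=(5,))[0]
    F, (df1, df2), p = nested_f_test(fit, fit)
    assert F == 0.0 and df1 == 0 and p == 1.0


def test_nested_f_hand_computed_oracle():
    """F matches a from-scratch residual-sum-of-squares computation."""
    rng = np.random.default_rng(0)
    n = 40
    cells = pd.DataFrame({
        "mu": rng.uniform(0, 1, n), "delta": rng.uniform(0, 1, n),
        "rho": rng.uniform(0, 1, n),
    })
    cells["D"] = 1 + cells["mu"] + rng.normal(0, 0.3, n)
    full = fit_model_suite(cells, models=(4,), rescale=False)[0]
    red = fit_model_suite(cells, models=(5,), rescale=False)[0]
    F, (df1, df2), p = nested_f_test(full, red)
    F_hand = ((red.rss - full.rss) / 1) / (full.rss / full.df_resid)
    assert F == pytest.approx(F_hand, rel=1e-12)
    assert (df1, df2) == (1, full.df_resid)
    assert p == pytest.approx(float(stats.f.sf(F_hand, 1, full.df_resid)), rel=1e-12)


def test_nested_f_rejects_non_nested():
    cells = gen_richness_survey(n_cells=50, noise_sd=1.0, seed=2)
    m1, m3 = fit_model_suite(cells, models=(1, 3))
    with pytest.raises(ValueError):
        nested_f_test(m1, m3)


def test_nested_f_null_p_values_are_uniform():
    """Adding a pure-noise regressor: p-values uniform under the null."""
    pvals = []
    for seed in range(200):
        rng = np.random.default_rng(seed)
        n = 60
        x = rng.uniform(0, 1, n)
        noise_col = rng.uniform(0, 1, n)
        y = 1.0 + 2.0 * x + rng.normal(0, 1, n)
        cells = pd.DataFrame({"D": y, "mu": x, "delta": noise_col})
        full = fit_model_suite(cells, models=(5,), rescale=False)[0]
        # reduced: drop the noise (delta) term -> fit mu + mu2 only
        red_cells = cells.assign(delta=0.0)
        import statsmodels.api as sm
        X = sm.add_constant(pd.DataFrame({"mu": x, "mu2": x ** 2}))
        res = sm.OLS(y, X).fit()
        F = ((res.ssr - full.rss) / 1) / (full.rss / full.df_resid)
        pvals.append(float(stats.f.sf(F, 1, full.df_resid)))
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01


def test_intercept_only_f_matches_from_scratch():
    cells = gen_richness_survey(n_cells=80, noise_sd=3.0, seed=5)
    fit = fit_model_suite(cells, models=(5,))[0]
    y = cells["D"].to_numpy()
    rss0 = float(np.sum((y - y.mean()) ** 2))
    k = len(fit.terms)
    F_hand = ((rss0 - fit.rss) / k) / (fit.rss / fit.df_resid)
    assert fit.f_statistic == pytest.approx(F_hand, rel=1e-9)


def test_border_cell_filter():
    cells = pd.DataFrame({"coverage": [1.0, 0.4, 1.0], "D": [1, 2, 3]})
    kept = border_cell_filter(cells)
    assert list(kept["D"]) == [1, 3]
    assert len(border_cell_filter(cells, threshold=0.0)) == 3
    with pytest.raises(ValueError):
        border_cell_filter(pd.DataFrame({"coverage": [1.5]}))
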