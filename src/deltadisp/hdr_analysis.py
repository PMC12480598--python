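"""Warp-grid experiment and the richness regression model suite.

A theoretical species-richness surface

    D = b0 + b_mu * mu + b_mu2 * mu^2 + b_delta * delta (+ b_delta2 * delta^2)

combines a hump-shaped mean-diversity relationship with a monotonic
positive heterogeneity-diversity relationship.  Evaluating every
heterogeneity measure analytically on a Cartesian (mu, delta) grid
shows how mean-biased measures warp this surface: quadratic fits of D
on range-, sd- or CV-based heterogeneity acquire spurious hump shapes,
while the delta-based fit stays linear.

The model suite mirrors the five-elevation-model comparison used for
the Catalonia breeding-bird reanalysis:

    #1  D ~ rho + rho^2
    #2  D ~ mu + mu^2 + rho + rho^2
    #3  D ~ delta + delta^2
    #4  D ~ mu + mu^2 + delta + delta^2
    #5  D ~ mu + mu^2 + delta

with predictors min-max rescaled to [0, 1] before fitting (OLS via
statsmodels), plus nested extra-sum-of-squares F-tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import analytic_measures as am
from .distributions import (
    BetaSpec,
    Boundedness,
    BoundsSpec,
    GammaSpec,
    classify_bounds,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RichnessModelSpec",
    "CATALONIA_RICHNESS",
    "ModelFit",
    "richness_truth",
    "make_warp_grid",
    "fit_quadratic_hdr",
    "fit_model_suite",
    "nested_f_test",
    "border_cell_filter",
    "MODEL_TERMS",
]


@dataclass(frozen=True)
class RichnessModelSpec:
    """Coefficients of the theoretical richness surface, raw scales."""

    intercept: float
    mean_linear: float
    mean_quadratic: float
    delta_linear: float
    delta_quadratic: float = 0.0


#: the Catalonia-calibrated surface: intercept 66.395, hump-shaped mean
#: relationship, monotonic positive delta relationship (no delta^2 term)
CATALONIA_RICHNESS = RichnessModelSpec(
    intercept=66.395,
    mean_linear=3.034e-2,
    mean_quadratic=-1.188e-5,
    delta_linear=1.076e-1,
)


def richness_truth(mu, delta, spec: RichnessModelSpec = CATALONIA_RICHNESS):
    """Deterministic richness D at (mu, delta); vectorized."""
    mu = np.asarray(mu, dtype=float)
    delta = np.asarray(delta, dtype=float)
    out = (
        spec.intercept
        + spec.mean_linear * mu
        + spec.mean_quadratic * mu * mu
        + spec.delta_linear * delta
        + spec.delta_quadratic * delta * delta
    )
    return float(out) if out.ndim == 0 else out


def make_warp_grid(
    mu_range: tuple[float, float] = (64.0, 2422.0),
    delta_range: tuple[float, float] = (0.64, 144.0),
    n_per_axis: int = 7,
    family: str = "gamma",
    bounds: Optional[BoundsSpec] = None,
    spec: RichnessModelSpec = CATALONIA_RICHNESS,
) -> pd.DataFrame:
    """Cartesian (mu, delta) grid with richness and every analytic measure.

    Defaults follow the theoretical experiment: means between 64 and
    2422 (elevation-like, gamma family with L = 0) crossed with delta
    between 0.64 and 144.0.  Gamma measures are evaluated with
    vectorized closed forms; the quantile range uses the array Newton
    solver, so the 500x500 polynomial-fitting grid stays cheap.
    """
    if n_per_axis < 2:
        raise ValueError("need at least 2 grid points per axis")
    mus = np.linspace(mu_range[0], mu_range[1], n_per_axis)
    deltas = np.linspace(delta_range[0], delta_range[1], n_per_axis)
    mu_g, d_g = np.meshgrid(mus, deltas, indexing="ij")
    mu_f, d_f = mu_g.ravel(), d_g.ravel()
    if family == "gamma":
        if bounds is None:
            bounds = BoundsSpec(lower=0.0)
        mu_std = mu_f - bounds.lower if bounds.lower is not None else bounds.upper - mu_f
        k = mu_std / d_f
        var = mu_std * d_f
        df = pd.DataFrame({
            "mu": mu_f,
            "delta": d_f,
            "richness": richness_truth(mu_f, d_f, spec),
            "sd": np.sqrt(var),
            "variance": var,
            "cv": 1.0 / np.sqrt(k),
            "gini": am._gamma_gini(k),
            "entropy": am._gamma_entropy(k, d_f),
            "range": am._gamma_qrange95(k, d_f),
        })
    elif family == "beta":
        if bounds is None:
            bounds = BoundsSpec(0.0, 1.0)
        w = bounds.width
        mu_std = (mu_f - bounds.lower) / w
        if np.any((mu_std <= 0) | (mu_std >= 1)) or np.any((d_f <= 0) | (d_f >= 1)):
            raise ValueError("beta warp grid requires standardized means and deltas in (0,1)")
        conc = 1.0 / d_f - 1.0
        p, q = mu_std * conc, (1.0 - mu_std) * conc
        var = d_f * mu_std * (1.0 - mu_std)
        df = pd.DataFrame({
            "mu": mu_f,
            "delta": d_f,
            "richness": richness_truth(mu_f, d_f, spec),
            "sd": np.sqrt(var) * w,
            "variance": var * w * w,
            "cv": np.sqrt(var) / mu_std,
            "gini": am._beta_gini(p, q),
            "entropy": am._beta_entropy(p, q) + math.log(w),
            "range": am._beta_qrange95(p, q, width=w),
        })
    else:
        raise ValueError(f"unknown family {family!r}")
    n_bad = int((~np.isfinite(df.drop(columns=["mu", "delta"])).all(axis=1)).sum())
    if n_bad:
        logger.warning("dropping %d warp-grid records with undefined measures", n_bad)
        df = df[np.isfinite(df.drop(columns=["mu", "delta"])).all(axis=1)]
    return df.reset_index(drop=True)


@dataclass
class ModelFit:
    """OLS fit record with everything the model comparison needs."""

    tag: str
    terms: tuple[str, ...]
    params: dict
    bse: dict
    tvalues: dict
    pvalues: dict
    adj_r2: float
    n: int
    rss: float
    df_resid: int
    f_statistic: float
    f_pvalue: float
    residuals: np.ndarray = field(repr=False)
    scaling: dict = field(default_factory=dict)


def _ols_fit(y: np.ndarray, X: pd.DataFrame, tag: str, scaling: dict) -> ModelFit:
    exog = sm.add_constant(X, has_constant="add")
    res = sm.OLS(y, exog).fit()
    return ModelFit(
        tag=tag,
        terms=tuple(c for c in exog.columns if c != "const"),
        params=dict(res.params),
        bse=dict(res.bse),
        tvalues=dict(res.tvalues),
        pvalues=dict(res.pvalues),
        adj_r2=float(res.rsquared_adj),
        n=int(res.nobs),
        rss=float(res.ssr),
        df_resid=int(res.df_resid),
        f_statistic=float(res.fvalue),
        f_pvalue=float(res.f_pvalue),
        residuals=np.asarray(res.resid),
        scaling=scaling,
    )


def fit_quadratic_hdr(records: pd.DataFrame, measure: str,
                      response: str = "richness", rescale: bool = True) -> ModelFit:
    """Second-degree polynomial OLS of richness on one heterogeneity measure.

    The measure is min–max rescaled before fitting (quadratic
    coefficient sign is invariant to this), so the quadratic/linear
    coefficient ratio is comparable across measures.
    """
    if len(records) < 6:
        raise ValueError("need at least 6 records")
    x = records[measure].to_numpy(dtype=float)
    y = records[response].to_numpy(dtype=float)
    scaling = {}
    if rescale:
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi <= lo:
            raise ValueError(f"measure {measure!r} is constant; quadratic fit is rank-deficient")
        scaling[measure] = (lo, hi)
        x = (x - lo) / (hi - lo)
    X = pd.DataFrame({measure: x, f"{measure}2": x * x})
    if np.linalg.matrix_rank(np.column_stack([np.ones_like(x), X.to_numpy()])) < 3:
        raise ValueError("rank-deficient quadratic design")
    return _ols_fit(y, X, tag=f"quadratic:{measure}", scaling=scaling)


MODEL_TERMS = {
    1: ("rho", "rho2"),
    2: ("mu", "mu2", "rho", "rho2"),
    3: ("delta", "delta2"),
    4: ("mu", "mu2", "delta", "delta2"),
    5: ("mu", "mu2", "delta"),
}

_BASE_OF = {"mu": "mu", "mu2": "mu", "delta": "delta", "delta2": "delta",
            "rho": "rho", "rho2": "rho"}


def fit_model_suite(
    cells: pd.DataFrame,
    models: Sequence[int] = (1, 2, 3, 4, 5),
    response: str = "D",
    rescale: bool = True,
) -> list[ModelFit]:
    """The five richness models, predictors min–max rescaled to [0, 1].

    ``cells`` needs columns D, mu, delta (and rho for models #1/#2).
    Quadratic terms are squares of the rescaled base predictor.  The
    per-model F statistic against the intercept-only model is recorded
    on each fit; the rescaling constants are stored under ``scaling``
    so coefficients can be mapped back to raw units.
    """
    if len(cells) < 20:
        raise ValueError("need at least 20 cells")
    needed = {response} | {_BASE_OF[t] for m in models for t in MODEL_TERMS[m]}
    missing = needed - set(cells.columns)
    if missing:
        raise ValueError(f"cells table missing columns: {sorted(missing)}")
    y = cells[response].to_numpy(dtype=float)
    base = {}
    scaling = {}
    for col in sorted(needed - {response}):
        x = cells[col].to_numpy(dtype=float)
        if rescale:
            lo, hi = float(np.min(x)), float(np.max(x))
            if hi <= lo:
                raise ValueError(f"column {col!r} is constant")
            scaling[col] = (lo, hi)
            x = (x - lo) / (hi - lo)
        base[col] = x
    fits = []
    for m in models:
        terms = MODEL_TERMS[m]
        X = pd.DataFrame({
            t: base[_BASE_OF[t]] if not t.endswith("2") else base[_BASE_OF[t]] ** 2
            for t in terms
        })
        fit = _ols_fit(y, X, tag=f"#{m}", scaling={c: scaling.get(c) for c in
                                                   {_BASE_OF[t] for t in terms}})
        fits.append(fit)
    return fits


def nested_f_test(fit_full: ModelFit, fit_reduced: ModelFit) -> tuple[float, tuple[int, int], float]:
    """Extra-sum-of-squares F comparing nested OLS fits.

    Requires the reduced model's terms to be a subset of the full
    model's and both fits to share n.  Returns (F, (df_num, df_den), p).
    """
    if not set(fit_reduced.terms) <= set(fit_full.terms):
        raise ValueError("models are not nested (reduced terms not a subset of full)")
    if fit_full.n != fit_reduced.n:
        raise ValueError("models were fit on different sample sizes")
    df_num = fit_reduced.df_resid - fit_full.df_resid
    df_den = fit_full.df_resid
    if df_num == 0:
        return 0.0, (0, df_den), 1.0
    F = ((fit_reduced.rss - fit_full.rss) / df_num) / (fit_full.rss / df_den)
    F = max(F, 0.0)
    p = float(stats.f.sf(F, df_num, df_den))
    return float(F), (df_num, df_den), p


def border_cell_filter(cells: pd.DataFrame, coverage_col: str = "coverage",
                       threshold: float = 1.0) -> pd.DataFrame:
    """Keep cells whose area coverage fraction meets the threshold.

    Border cells only partially covering the study region receive less
    sampling effort; the default threshold 1.0 keeps fully interior
    cells only.
    """
    cov = cells[coverage_col].to_numpy(dtype=float)
    if np.any((cov < 0) | (cov > 1)):
        raise ValueError("coverage fractions must lie in [0, 1]")
    return cells[cov >= threshold].reset_index(drop=True)
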