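"""Empirical mean-bias testing on tables of per-tile heterogeneity profiles.

Workflow: take a mean-balanced (stratified) resample of tiles, predict
each mean-biased measure from the tile mean using the analytic bias
model with the across-tile average delta,

    lower-bounded:  s = sqrt(dbar * xbar),  s^2 = dbar * xbar,
                    CV = sqrt(dmed * xbar) / xbar
    double-bounded: the same with xbar replaced by (xbar - L)(U - xbar),

compare against a null model (the across-tile mean of the observed
measure) with a paired t-test on squared errors, and run a TOST
equivalence test showing that delta's own dependence on the mean is
negligible (absolute slope less than half the reference measure's).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .distributions import Boundedness, BoundsSpec, classify_bounds

logger = logging.getLogger(__name__)

__all__ = [
    "BiasModelComparison",
    "EquivalenceResult",
    "mean_balanced_sample",
    "predict_measure_from_mean",
    "null_predict",
    "compare_paired_t",
    "compare_models",
    "delta_negligibility_test",
]

PREDICTABLE = ("sd", "variance", "cv")


@dataclass(frozen=True)
class BiasModelComparison:
    measure: str
    mse_analytic: float
    mse_null: float
    t_statistic: float
    df: int
    p_value: float
    delta_average_used: str
    exact_tie: bool = False


@dataclass(frozen=True)
class EquivalenceResult:
    delta_coefficient: float
    delta_se: float
    reference_coefficient: float
    negligible_bound: float
    t_statistic: float
    df: int
    p_value: float
    passed: bool


def mean_balanced_sample(
    tiles: pd.DataFrame,
    n_strata: int,
    per_stratum: int,
    mean_range: Optional[tuple[float, float]] = None,
    seed: Optional[int] = None,
    mean_col: str = "mean",
    mean_cap: Optional[float] = None,
    valid_fraction_col: Optional[str] = None,
    min_valid_fraction: float = 0.75,
) -> pd.DataFrame:
    """Two-phase stratified resample balancing the tile-mean distribution.

    Tiles are first filtered (optional valid-area fraction threshold and
    mean cap), then binned into ``n_strata`` evenly spaced strata over
    ``mean_range`` and resampled up to ``per_stratum`` tiles per stratum
    (with replacement when a stratum is short).  Empty strata are
    skipped with a warning.
    """
    if n_strata < 2:
        raise ValueError("need at least 2 strata")
    rng = np.random.default_rng(seed)
    df = tiles
    if valid_fraction_col is not None:
        df = df[df[valid_fraction_col] >= min_valid_fraction]
    if mean_cap is not None:
        df = df[df[mean_col] <= mean_cap]
    means = df[mean_col].to_numpy()
    if mean_range is None:
        mean_range = (float(means.min()), float(means.max()))
    edges = np.linspace(mean_range[0], mean_range[1], n_strata + 1)
    in_range = (means >= edges[0]) & (means <= edges[-1])
    df = df[in_range]
    means = means[in_range]
    strata = np.clip(np.searchsorted(edges, means, side="right") - 1, 0, n_strata - 1)
    picks = []
    for s in range(n_strata):
        idx = np.flatnonzero(strata == s)
        if idx.size == 0:
            logger.warning("stratum %d of %d is empty; skipped", s, n_strata)
            continue
        chosen = rng.choice(idx, size=per_stratum, replace=idx.size < per_stratum)
        picks.append(chosen)
    if not picks:
        raise ValueError("all strata empty")
    return df.iloc[np.concatenate(picks)].reset_index(drop=True)


def _mean_predictor(xbar: np.ndarray, bounds: BoundsSpec) -> np.ndarray:
    """(xbar - L), or (xbar - L)(U - xbar), the delta-free mean term."""
    cls = classify_bounds(bounds)
    if cls is Boundedness.DOUBLE:
        return (xbar - bounds.lower) * (bounds.upper - xbar)
    if cls is Boundedness.LOWER:
        return xbar - bounds.lower
    if cls is Boundedness.UPPER:
        return bounds.upper - xbar
    raise ValueError("bias prediction requires at least one bound")


def predict_measure_from_mean(
    tiles: pd.DataFrame,
    measure: str,
    bounds: BoundsSpec,
    delta_average: Optional[str] = None,
    mean_col: str = "mean",
    delta_col: str = "delta",
) -> np.ndarray:
    """Analytic prediction of sd / variance / CV from each tile's mean.

    The across-tile mean of delta-hat drives the sd and variance
    predictions; the median drives the CV (the CV diverges at small
    means, making the median the more robust average there).  Tiles with
    means on a bound receive NaN predictions.
    """
    if measure not in PREDICTABLE:
        raise ValueError(f"measure must be one of {PREDICTABLE}, got {measure!r}")
    if delta_average is None:
        delta_average = "median" if measure == "cv" else "mean"
    deltas = tiles[delta_col].to_numpy(dtype=float)
    dbar = float(np.nanmedian(deltas) if delta_average == "median" else np.nanmean(deltas))
    xbar = tiles[mean_col].to_numpy(dtype=float)
    g = _mean_predictor(xbar, bounds)
    with np.errstate(invalid="ignore", divide="ignore"):
        if measure == "variance":
            pred = dbar * g
        elif measure == "sd":
            pred = np.sqrt(dbar * g)
        else:  # cv
            pred = np.sqrt(dbar * g) / xbar
    pred = np.where(g > 0, pred, np.nan)
    return pred


def null_predict(tiles: pd.DataFrame, measure: str) -> np.ndarray:
    """Null model: every prediction is the across-tile mean of the measure."""
    obs = tiles[measure].to_numpy(dtype=float)
    if obs.size < 1:
        raise ValueError("need at least one tile")
    return np.full(obs.shape, float(np.nanmean(obs)))


def compare_paired_t(
    squared_errors_a,
    squared_errors_b,
    measure: str = "",
    delta_average_used: str = "",
) -> BiasModelComparison:
    """Two-sided paired t-test on per-tile squared-error differences.

    Exactly tied error vectors produce t = 0, p = 1; zero-variance
    nonzero differences produce an infinite t (sentinel) with the
    ``exact_tie`` flag left False.
    """
    a = np.asarray(squared_errors_a, dtype=float)
    b = np.asarray(squared_errors_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need equal-length paired vectors with n >= 2")
    d = a - b
    n = d.size
    sd = d.std(ddof=1)
    mean_d = d.mean()
    if sd == 0.0:
        if mean_d == 0.0:
            t, p, tie = 0.0, 1.0, True
        else:
            t = math.copysign(math.inf, mean_d)
            p, tie = 0.0, False
    else:
        t = mean_d / (sd / math.sqrt(n))
        p = 2.0 * stats.t.sf(abs(t), df=n - 1)
        tie = False
    return BiasModelComparison(
        measure=measure,
        mse_analytic=float(np.mean(a)),
        mse_null=float(np.mean(b)),
        t_statistic=float(t),
        df=n - 1,
        p_value=float(p),
        delta_average_used=delta_average_used,
        exact_tie=tie,
    )


def compare_models(
    tiles: pd.DataFrame,
    measure: str,
    bounds: BoundsSpec,
    mean_col: str = "mean",
    delta_col: str = "delta",
) -> BiasModelComparison:
    """Analytic bias model vs null model for one measure on a tile table."""
    delta_average = "median" if measure == "cv" else "mean"
    pred = predict_measure_from_mean(tiles, measure, bounds,
                                     delta_average=delta_average,
                                     mean_col=mean_col, delta_col=delta_col)
    obs = tiles[measure].to_numpy(dtype=float)
    ok = np.isfinite(pred) & np.isfinite(obs)
    err_analytic = (obs[ok] - pred[ok]) ** 2
    err_null = (obs[ok] - null_predict(tiles[ok], measure)) ** 2
    return compare_paired_t(err_analytic, err_null, measure=measure,
                            delta_average_used=delta_average)


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = np.nanmin(x), np.nanmax(x)
    if hi <= lo:
        raise ValueError("degenerate (constant) column cannot be rescaled")
    return (x - lo) / (hi - lo)


def _ols_slope(y: np.ndarray, x: np.ndarray) -> tuple[float, float, int]:
    """Slope, its standard error and residual df of y ~ 1 + x."""
    X = np.column_stack([np.ones_like(x), x])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    df = y.size - 2
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return float(coef[1]), float(math.sqrt(cov[1, 1])), df


def delta_negligibility_test(
    tiles: pd.DataFrame,
    reference_measure: str,
    bounds: BoundsSpec,
    alpha: float = 0.05,
    mean_col: str = "mean",
    delta_col: str = "delta",
    response_col: Optional[str] = None,
) -> EquivalenceResult:
    """TOST equivalence test of delta's mean-dependence.

    Both delta-hat and the reference measure are min–max rescaled to
    [0, 1]; each is regressed on the mean-derived predictor of the
    reference measure's bias-model form (sd, variance or CV form with
    the delta factor removed).  Two one-sided tests then ask whether
    delta's coefficient lies within +/- half the absolute reference
    coefficient; ``passed`` means negligibility is established at
    ``alpha``.  ``response_col`` substitutes another column for delta
    (useful as a negative control).
    """
    if reference_measure not in PREDICTABLE:
        raise ValueError(f"reference measure must be one of {PREDICTABLE}")
    if len(tiles) < 10:
        raise ValueError("need at least 10 tiles")
    xbar = tiles[mean_col].to_numpy(dtype=float)
    g = _mean_predictor(xbar, bounds)
    with np.errstate(invalid="ignore", divide="ignore"):
        if reference_measure == "sd":
            pred = np.sqrt(g)
        elif reference_measure == "variance":
            pred = g
        else:
            pred = np.sqrt(g) / xbar
    resp_col = delta_col if response_col is None else response_col
    y_delta = tiles[resp_col].to_numpy(dtype=float)
    y_ref = tiles[reference_measure].to_numpy(dtype=float)
    ok = np.isfinite(pred) & np.isfinite(y_delta) & np.isfinite(y_ref)
    pred_r = _minmax(pred[ok])
    b_delta, se_delta, df = _ols_slope(_minmax(y_delta[ok]), pred_r)
    b_ref, _, _ = _ols_slope(_minmax(y_ref[ok]), pred_r)
    bound = abs(b_ref) / 2.0
    if se_delta == 0.0:
        passed = abs(b_delta) < bound
        t_binding, p = math.copysign(math.inf, -1 if passed else 1), (0.0 if passed else 1.0)
    else:
        t_lower = (b_delta + bound) / se_delta   # H0: b <= -bound
        t_upper = (b_delta - bound) / se_delta   # H0: b >= +bound
        p_lower = stats.t.sf(t_lower, df=df)
        p_upper = stats.t.cdf(t_upper, df=df)
        if p_lower >= p_upper:
            p, t_binding = float(p_lower), float(t_lower)
        else:
            p, t_binding = float(p_upper), float(t_upper)
        passed = p < alpha
    return EquivalenceResult(
        delta_coefficient=float(b_delta),
        delta_se=float(se_delta),
        reference_coefficient=float(b_ref),
        negligible_bound=float(bound),
        t_statistic=t_binding,
        df=df,
        p_value=p,
        passed=bool(passed),
    )
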