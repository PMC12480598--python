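"""Closed-form heterogeneity measures for beta/gamma parameter points.

These are the analytic mean-bias curves: with dispersion (delta) held
fixed, every commonly used heterogeneity measure except delta itself
moves as a function of the mean.  Closed forms:

* CV:       beta  sqrt(sigma^2)*(p+q)/p;   gamma  1/sqrt(k)
* skewness: gamma 2/sqrt(k) = 2*CV
* Gini:     beta  2*B(2p,2q)/[p*B(p,q)^2]; gamma  Gamma(k+1/2)/[sqrt(pi)*Gamma(k+1)]
* entropy:  beta  ln B(p,q) - (p-1)[psi(p)-psi(p+q)] - (q-1)[psi(q)-psi(p+q)]
            gamma k + ln(delta_L) + ln Gamma(k) + (1-k) psi(k)
* 0.95 quantile range: x_{0.975} - x_{0.025} from the quantile function,
  solved by Newton's method seeded at the mode (tolerance 1e-12) with a
  bisection fallback.

Scale conventions: CV, Gini and skewness are computed on the
standardized variable (a location shift changes both, so only the
standard form is meaningful); sd, variance and the quantile range are
returned in the raw units of the declared bounds; differential entropy
picks up the change-of-variables term ln(U - L) for general
double-bounded variables and nothing for pure location shifts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, special

from .distributions import (
    BetaSpec,
    Boundedness,
    BoundsSpec,
    DistSpec,
    GammaSpec,
    MeanDispersion,
    beta_from_mean_dispersion,
    beta_moments,
    classify_bounds,
    dist_mode,
    gamma_from_mean_dispersion,
    gamma_moments,
    standardize,
)

logger = logging.getLogger(__name__)

__all__ = [
    "HeterogeneityProfile",
    "analytic_cv",
    "analytic_skewness",
    "analytic_gini",
    "analytic_entropy",
    "quantile_range_95",
    "analytic_profile",
    "bias_curve",
    "bias_curves",
    "MEASURES",
]

MEASURES = ("sd", "variance", "cv", "gini", "entropy", "range", "delta")


@dataclass(frozen=True)
class HeterogeneityProfile:
    """The six common heterogeneity measures plus delta at one point."""

    sd: float
    variance: float
    cv: float
    gini: float
    entropy: float
    qrange95: float
    delta: float


def analytic_cv(spec: DistSpec) -> float:
    """Coefficient of variation on the standardized scale."""
    if isinstance(spec, BetaSpec):
        mu, var, _ = beta_moments(spec)
        return math.sqrt(var) / mu
    return 1.0 / math.sqrt(spec.k)


def analytic_skewness(spec: GammaSpec) -> float:
    """Gamma skewness 2/sqrt(k); identically twice the gamma CV."""
    return 2.0 / math.sqrt(spec.k)


def analytic_gini(spec: DistSpec) -> float:
    """Gini coefficient of the standardized variable.

    Evaluated in log-gamma space so large shape parameters do not
    overflow the beta/gamma functions.
    """
    if isinstance(spec, BetaSpec):
        return float(_beta_gini(spec.p, spec.q))
    return float(_gamma_gini(spec.k))


def _beta_gini(p, q):
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    # 2 B(2p, 2q) / (p B(p, q)^2)
    log_g = math.log(2.0) + special.betaln(2 * p, 2 * q) - np.log(p) - 2.0 * special.betaln(p, q)
    return np.exp(log_g)


def _gamma_gini(k):
    k = np.asarray(k, dtype=float)
    # Gamma(k + 1/2) / (sqrt(pi) Gamma(k + 1))
    log_g = special.gammaln(k + 0.5) - 0.5 * math.log(math.pi) - special.gammaln(k + 1.0)
    return np.exp(log_g)


def analytic_entropy(spec: DistSpec) -> float:
    """Differential entropy in nats on the raw scale of the bounds."""
    if isinstance(spec, BetaSpec):
        h = float(_beta_entropy(spec.p, spec.q))
        return h + math.log(spec.bounds.width)
    return float(_gamma_entropy(spec.k, spec.dispersion))


def _beta_entropy(p, q):
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    psum = special.digamma(p + q)
    return (
        special.betaln(p, q)
        - (p - 1.0) * (special.digamma(p) - psum)
        - (q - 1.0) * (special.digamma(q) - psum)
    )


def _gamma_entropy(k, scale):
    k = np.asarray(k, dtype=float)
    return k + np.log(scale) + special.gammaln(k) + (1.0 - k) * special.digamma(k)


# ---------------------------------------------------------------------------
# quantile solver


def _newton_quantile(prob, x0, cdf, pdf_, lo, hi, tol=1e-12, max_iter=100):
    """Vectorized safeguarded Newton solve of F(x) = prob.

    Steps are clamped to the open support by halving toward the violated
    edge; elements that do not converge are flagged for bisection.
    """
    x = np.array(np.broadcast_to(np.asarray(x0, dtype=float), np.shape(prob)), dtype=float)
    prob = np.asarray(prob, dtype=float)
    active = np.ones(x.shape, dtype=bool)
    for _ in range(max_iter):
        f = cdf(x) - prob
        active &= np.abs(f) > tol
        if not active.any():
            break
        d = pdf_(x)
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(active & (d > 0) & np.isfinite(d), f / np.where(d > 0, d, 1.0), 0.0)
        x_new = x - step
        # clamp into the open support by halving toward the edge
        bad_lo = active & (x_new <= lo)
        bad_hi = active & (x_new >= hi) if np.isfinite(hi) else np.zeros_like(bad_lo)
        x_new = np.where(bad_lo, 0.5 * (x + lo), x_new)
        x_new = np.where(bad_hi, 0.5 * (x + hi), x_new)
        stalled = active & ((d <= 0) | ~np.isfinite(d))
        x = np.where(active & ~stalled, x_new, x)
    return x, np.abs(cdf(x) - prob) > tol


def _bisect_scalar(prob, cdf, lo, hi):
    if not np.isfinite(hi):
        # expand an upper bracket for the gamma tail
        hi = max(1.0, 2.0 * lo if lo > 0 else 1.0)
        while cdf(hi) < prob:
            hi *= 2.0
            if hi > 1e308:
                raise RuntimeError("bisection bracket expansion failed")
    return optimize.brentq(lambda t: cdf(t) - prob, lo, hi, xtol=1e-14, rtol=8.9e-16)


def _beta_quantile(p, q, prob):
    """Quantile of the standard beta at probabilities ``prob`` (array ok)."""
    p_arr, q_arr, prob_arr = np.broadcast_arrays(
        np.asarray(p, float), np.asarray(q, float), np.asarray(prob, float)
    )
    spec0 = BetaSpec(float(p_arr.flat[0]), float(q_arr.flat[0]))
    if p_arr.size == 1:
        x0 = standardize(dist_mode(spec0), spec0.bounds)
        x0 = min(max(x0, 1e-9), 1.0 - 1e-9)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            x0 = np.where(
                (p_arr > 1) & (q_arr > 1),
                (p_arr - 1.0) / (p_arr + q_arr - 2.0),
                np.where(p_arr <= q_arr, 1e-9, 1.0 - 1e-9),
            )
    cdf = lambda x: special.betainc(p_arr, q_arr, np.clip(x, 0.0, 1.0))
    pdf_ = lambda x: _safe_beta_pdf(x, p_arr, q_arr)
    x, failed = _newton_quantile(prob_arr, x0, cdf, pdf_, 0.0, 1.0)
    x = _fallback(x, failed, prob_arr, lambda i: (
        lambda t: float(special.betainc(p_arr.flat[i], q_arr.flat[i], t))), 0.0, 1.0)
    return x if np.ndim(prob) or np.ndim(p) else float(x)


def _gamma_quantile(k, prob):
    """Quantile of the standard gamma (scale 1) at probabilities ``prob``."""
    k_arr, prob_arr = np.broadcast_arrays(np.asarray(k, float), np.asarray(prob, float))
    x0 = np.where(k_arr >= 1.0, k_arr - 1.0, 0.0)
    x0 = np.maximum(x0, 1e-9)
    cdf = lambda x: special.gammainc(k_arr, np.maximum(x, 0.0))
    pdf_ = lambda x: _safe_gamma_pdf(x, k_arr)
    x, failed = _newton_quantile(prob_arr, x0, cdf, pdf_, 0.0, np.inf)
    x = _fallback(x, failed, prob_arr, lambda i: (
        lambda t: float(special.gammainc(k_arr.flat[i], t))), 0.0, np.inf)
    return x if np.ndim(prob) or np.ndim(k) else float(x)


def _fallback(x, failed, prob_arr, cdf_factory, lo, hi):
    if failed.any():
        x = np.array(x, dtype=float)
        for i in np.flatnonzero(failed.ravel()):
            x.flat[i] = _bisect_scalar(prob_arr.flat[i], cdf_factory(i), lo, hi)
    return x


def _safe_beta_pdf(x, p, q):
    x = np.clip(x, 1e-300, 1.0 - 1e-16)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        return np.exp(
            special.xlogy(p - 1.0, x) + special.xlog1py(q - 1.0, -x) - special.betaln(p, q)
        )


def _safe_gamma_pdf(x, k):
    x = np.maximum(x, 1e-300)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        return np.exp(special.xlogy(k - 1.0, x) - x - special.gammaln(k))


def quantile_range_95(spec: DistSpec) -> float:
    """Extent between the 0.025 and 0.975 quantiles, raw units.

    Newton from the mode at tolerance 1e-12 with automatic bisection
    fallback.  Invariant under location shifts and reflection, so the
    flipped gamma shares the standard gamma's range.
    """
    if isinstance(spec, BetaSpec):
        lo_q = _beta_quantile(spec.p, spec.q, 0.025)
        hi_q = _beta_quantile(spec.p, spec.q, 0.975)
        return (hi_q - lo_q) * spec.bounds.width
    lo_q = _gamma_quantile(spec.k, 0.025)
    hi_q = _gamma_quantile(spec.k, 0.975)
    return (hi_q - lo_q) * spec.dispersion


def _gamma_qrange95(k, scale):
    """Vectorized gamma 0.95 quantile range (used by the warp grid)."""
    return (_gamma_quantile(k, np.full(np.shape(k), 0.975)) -
            _gamma_quantile(k, np.full(np.shape(k), 0.025))) * np.asarray(scale, float)


def _beta_qrange95(p, q, width=1.0):
    return (_beta_quantile(p, q, np.full(np.shape(p), 0.975)) -
            _beta_quantile(p, q, np.full(np.shape(p), 0.025))) * width


# ---------------------------------------------------------------------------
# profiles and bias curves


def analytic_profile(spec: DistSpec) -> HeterogeneityProfile:
    """All measures (raw-scale sd/variance/range, standardized CV/Gini)."""
    if isinstance(spec, BetaSpec):
        mu, var, d2 = beta_moments(spec)
        w = spec.bounds.width
        return HeterogeneityProfile(
            sd=math.sqrt(var) * w,
            variance=var * w * w,
            cv=analytic_cv(spec),
            gini=analytic_gini(spec),
            entropy=analytic_entropy(spec),
            qrange95=quantile_range_95(spec),
            delta=d2,
        )
    mu, var = gamma_moments(spec)
    return HeterogeneityProfile(
        sd=math.sqrt(var),
        variance=var,
        cv=analytic_cv(spec),
        gini=analytic_gini(spec),
        entropy=analytic_entropy(spec),
        qrange95=quantile_range_95(spec),
        delta=spec.dispersion,
    )


def _spec_at(mean: float, delta: float, bounds: BoundsSpec) -> DistSpec:
    cls = classify_bounds(bounds)
    md = MeanDispersion(mean=mean, delta=delta)
    if cls is Boundedness.DOUBLE:
        return beta_from_mean_dispersion(md, bounds)
    if cls in (Boundedness.LOWER, Boundedness.UPPER):
        return gamma_from_mean_dispersion(md, bounds)
    raise ValueError("bias curves require at least one bound")


def _measure_value(spec: DistSpec, measure: str) -> float:
    prof = analytic_profile(spec)
    return {
        "sd": prof.sd,
        "variance": prof.variance,
        "cv": prof.cv,
        "gini": prof.gini,
        "entropy": prof.entropy,
        "range": prof.qrange95,
        "delta": prof.delta,
    }[measure]


def bias_curve(measure: str, bounds: BoundsSpec, delta: float, means: Sequence[float]):
    """Measure values along a mean grid at fixed delta.

    Returns a pandas DataFrame with columns (mean, value); means where
    the measure is undefined yield NaN with a logged warning.  For delta
    itself the curve is flat by construction — the mean-independence of
    the dispersion parameter.
    """
    import pandas as pd

    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")
    values = []
    for m in means:
        try:
            values.append(_measure_value(_spec_at(float(m), delta, bounds), measure))
        except (ValueError, RuntimeError) as exc:
            logger.warning("measure %s undefined at mean %s: %s", measure, m, exc)
            values.append(math.nan)
    return pd.DataFrame({"mean": np.asarray(means, dtype=float), "value": values})


def bias_curves(measures: Sequence[str], bounds: BoundsSpec, delta: float,
                means: Sequence[float]):
    """Long-format table (mean, measure, value) over several measures."""
    import pandas as pd

    frames = []
    for measure in measures:
        df = bias_curve(measure, bounds, delta, means)
        df.insert(1, "measure", measure)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
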