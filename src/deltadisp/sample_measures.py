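"""Finite-sample estimators of heterogeneity measures, including delta-hat.

The estimator of the mean-independent dispersion is the generalised

    delta = s^2 / [(xbar - L)^1(L) * (U - xbar)^1(U)]

where each indicator exponent is 1 when the corresponding bound is a
real number and 0 otherwise, so absent bounds drop out of the
denominator: delta2 for double-bounded variables, delta_L / delta_U for
single-bounded ones, and the variance itself for unbounded ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import spatial, special

from .distributions import Boundedness, BoundsSpec, classify_bounds, standardize

__all__ = [
    "SampleSummary",
    "summarize",
    "delta_hat",
    "cv_hat",
    "gini_hat",
    "qrange_hat",
    "knn_entropy_hat",
    "band_shannon_hat",
    "profile",
    "profile_table",
]


@dataclass(frozen=True)
class SampleSummary:
    n: int
    mean: float
    variance: float
    minimum: float
    maximum: float
    ddof: int = 1


def summarize(values, bounds: Optional[BoundsSpec] = None, ddof: int = 1) -> SampleSummary:
    """Sample mean/variance/extrema under a pinned variance convention.

    ``ddof=1`` (denominator n-1) is the default; values outside the
    declared bounds raise with the offending row indices.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise ValueError("values must be a nonempty 1-d array")
    if bounds is not None:
        lo = -math.inf if bounds.lower is None else bounds.lower
        hi = math.inf if bounds.upper is None else bounds.upper
        bad = np.flatnonzero((x < lo) | (x > hi))
        if bad.size:
            raise ValueError(
                f"{bad.size} value(s) outside bounds [{lo}, {hi}] at indices "
                f"{bad[:20].tolist()}{'...' if bad.size > 20 else ''}"
            )
    var = float(np.var(x, ddof=ddof)) if x.size > ddof else 0.0
    return SampleSummary(
        n=int(x.size),
        mean=float(np.mean(x)),
        variance=var,
        minimum=float(np.min(x)),
        maximum=float(np.max(x)),
        ddof=ddof,
    )


def delta_hat(summary: SampleSummary, bounds: BoundsSpec) -> float:
    """Mean-independent dispersion from a sample summary.

    A zero-variance sample has delta 0; a sample mean sitting exactly on
    a bound leaves delta undefined (the denominator vanishes) and raises.
    """
    cls = classify_bounds(bounds)
    if cls is Boundedness.UNBOUNDED:
        return summary.variance
    denom = 1.0
    if bounds.lower is not None:
        denom *= summary.mean - bounds.lower
    if bounds.upper is not None:
        denom *= bounds.upper - summary.mean
    if denom <= 0.0:
        if summary.variance == 0.0:
            return 0.0
        raise ValueError(
            f"sample mean {summary.mean} lies on a bound; delta is undefined"
        )
    return summary.variance / denom


def cv_hat(summary: SampleSummary) -> float:
    """Coefficient of variation s / xbar."""
    if summary.mean == 0.0:
        raise ValueError("CV undefined for zero sample mean")
    return math.sqrt(summary.variance) / summary.mean


def gini_hat(values) -> float:
    """Gini coefficient: half the relative mean absolute difference.

    Pair differences are taken over all ordered pairs including i = j
    (denominator 2 n^2 mu), evaluated via the sorted cumulative form in
    O(n log n).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 1:
        raise ValueError("empty sample")
    if np.any(x < 0):
        raise ValueError("gini_hat requires nonnegative (standardized) values")
    mu = float(np.mean(x))
    if mu == 0.0:
        if np.all(x == 0):
            return 0.0
        raise ValueError("Gini undefined for zero mean")
    i = np.arange(1, n + 1)
    return float(np.sum((2 * i - n - 1) * x) / (n * n * mu))


def qrange_hat(values, mode: str = "quantile") -> float:
    """Sample range: 0.025–0.975 quantile extent or min–max.

    ``quantile`` uses linear interpolation between order statistics;
    ``minmax`` is the convention of older heterogeneity studies that
    report the full observed extent.
    """
    x = np.asarray(values, dtype=float)
    if mode == "quantile":
        lo, hi = np.quantile(x, [0.025, 0.975])
        return float(hi - lo)
    if mode == "minmax":
        return float(np.max(x) - np.min(x))
    raise ValueError(f"unknown range mode {mode!r}; use 'quantile' or 'minmax'")


def knn_entropy_hat(values, k: int = 3) -> float:
    """Kozachenko–Leonenko differential entropy estimate in nats.

    H-hat = psi(n) - psi(k) + ln 2 + mean(ln eps_i), with eps_i the
    distance to the k-th nearest neighbour of point i.  Exact-duplicate
    distances are floored at machine-epsilon scale before the log.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if not (n > k >= 1):
        raise ValueError(f"need n > k >= 1, got n={n}, k={k}")
    tree = spatial.cKDTree(x[:, None])
    dist, _ = tree.query(x[:, None], k=k + 1)
    eps = dist[:, k]
    scale = max(float(np.ptp(x)), 1.0)
    eps = np.maximum(eps, np.finfo(float).eps * scale)
    return float(
        special.digamma(n) - special.digamma(k) + math.log(2.0) + np.mean(np.log(eps))
    )


def band_shannon_hat(values, band_edges) -> float:
    """Shannon entropy of band occupancy proportions, in nats.

    The banded analogue of foliage-height diversity: values are
    apportioned into contiguous bands and -sum p_i ln p_i is computed
    over occupancy proportions (empty bands contribute 0).
    """
    x = np.asarray(values, dtype=float)
    edges = np.asarray(band_edges, dtype=float)
    if edges.size < 2:
        raise ValueError("need at least one band (two edges)")
    if np.any(x < edges[0]) or np.any(x > edges[-1]):
        raise ValueError("values fall outside the band coverage")
    counts, _ = np.histogram(x, bins=edges)
    p = counts[counts > 0] / x.size
    return float(-np.sum(p * np.log(p)))


@dataclass
class SampleProfile:
    """All heterogeneity estimates for one unit (tile)."""

    n: int
    mean: float
    variance: float
    sd: float
    cv: Optional[float]
    gini: Optional[float]
    entropy: Optional[float]
    qrange95: float
    delta: Optional[float]
    errors: dict = field(default_factory=dict)


def profile(values, bounds: BoundsSpec, ddof: int = 1, range_mode: str = "quantile",
            knn_k: int = 3) -> SampleProfile:
    """Compute every estimator at once for one unit's sample.

    CV is computed on the raw values (s / xbar); Gini on the
    standardized values.  Per-measure failures are recorded under
    ``errors`` and reported as None rather than aborting the profile.
    """
    summary = summarize(values, bounds=bounds, ddof=ddof)
    errors: dict = {}

    def attempt(name, fn):
        try:
            return fn()
        except (ValueError, ZeroDivisionError) as exc:
            errors[name] = str(exc)
            return None

    x_std = standardize(np.asarray(values, dtype=float), bounds)
    return SampleProfile(
        n=summary.n,
        mean=summary.mean,
        variance=summary.variance,
        sd=math.sqrt(summary.variance),
        cv=attempt("cv", lambda: cv_hat(summary)),
        gini=attempt("gini", lambda: gini_hat(x_std)),
        entropy=attempt("entropy", lambda: knn_entropy_hat(values, k=knn_k)),
        qrange95=qrange_hat(values, mode=range_mode),
        delta=attempt("delta", lambda: delta_hat(summary, bounds)),
        errors=errors,
    )


def profile_table(obs, group_col: str, value_col: str, bounds: BoundsSpec,
                  ddof: int = 1, range_mode: str = "quantile", knn_k: int = 3):
    """Per-group profiles as a tidy DataFrame (one row per tile)."""
    import pandas as pd

    rows = []
    for gid, sub in obs.groupby(group_col, sort=True):
        prof = profile(sub[value_col].to_numpy(), bounds, ddof=ddof,
                       range_mode=range_mode, knn_k=knn_k)
        rows.append({
            group_col: gid,
            "n": prof.n,
            "mean": prof.mean,
            "variance": prof.variance,
            "sd": prof.sd,
            "cv": prof.cv,
            "gini": prof.gini,
            "entropy": prof.entropy,
            "qrange95": prof.qrange95,
            "delta": prof.delta,
        })
    return pd.DataFrame(rows)
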