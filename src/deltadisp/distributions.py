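"""Beta and gamma distributions parameterized by mean and dispersion.

Bounded continuous variables are modelled by the beta distribution (two
finite bounds) or the gamma distribution (one finite bound; the
upper-bounded case reflects the variable so the bound plays the role of
the gamma's zero).  Both families admit a (mean, delta) parameterization
in which ``delta`` is a pure dispersion parameter: for any fixed delta,
changing the mean moves the distribution without changing its
dispersion.  On the standard scales

* beta:  ``mu = p / (p + q)``, ``delta2 = 1 / (1 + p + q)``,
  ``sigma^2 = delta2 * mu * (1 - mu)``;
* gamma: ``mu = k * delta_L``, ``sigma^2 = mu * delta_L``.

General bounds enter only through an affine change of variable: a
double-bounded observation ``v`` on ``[L, U]`` indexes the standard beta
at ``x = (v - L)/(U - L)``; a lower-bounded one indexes the standard
gamma at ``x = v - L``; an upper-bounded one at ``x = U - v`` (a flipped
gamma).  For unbounded variables the dispersion is the variance itself
(the normal model), and no density machinery is provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Union

import numpy as np
from scipy import special

__all__ = [
    "Boundedness",
    "BoundsSpec",
    "BetaSpec",
    "GammaSpec",
    "MeanDispersion",
    "classify_bounds",
    "standardize",
    "destandardize",
    "beta_from_mean_dispersion",
    "beta_moments",
    "gamma_from_mean_dispersion",
    "gamma_moments",
    "pdf",
    "cdf",
    "dist_mode",
]

#: means closer than this to a bound are rejected (delta's denominator vanishes)
BOUND_TOL = 1e-12


class Boundedness(str, Enum):
    UNBOUNDED = "unbounded"
    LOWER = "lower"
    UPPER = "upper"
    DOUBLE = "double"


@dataclass(frozen=True)
class BoundsSpec:
    """Declared lower/upper bounds of a variable; either may be absent.

    Bounds are conceptual or experimental limits (cover percentage in
    [0, 100], elevation above sea level with L = 0, ...), not the
    observed sample minimum/maximum.
    """

    lower: Optional[float] = None
    upper: Optional[float] = None

    def __post_init__(self) -> None:
        for name, b in (("lower", self.lower), ("upper", self.upper)):
            if b is not None and not math.isfinite(b):
                raise ValueError(f"{name} bound must be finite or None, got {b}")
        if self.lower is not None and self.upper is not None:
            if not self.lower < self.upper:
                raise ValueError(
                    f"invalid bounds: lower ({self.lower}) must be < upper ({self.upper})"
                )

    @property
    def boundedness(self) -> Boundedness:
        return classify_bounds(self)

    @property
    def width(self) -> float:
        """U - L for double-bounded variables."""
        if self.lower is None or self.upper is None:
            raise ValueError("width requires both bounds")
        return self.upper - self.lower

    def contains(self, v: float, closed: bool = True) -> bool:
        lo = -math.inf if self.lower is None else self.lower
        hi = math.inf if self.upper is None else self.upper
        if closed:
            return lo <= v <= hi
        return lo < v < hi


def classify_bounds(bounds: BoundsSpec) -> Boundedness:
    """Boundedness class from which bounds are declared.

    This drives the indicator exponents of the generalised delta: each
    finite bound contributes one factor to delta's denominator.
    """
    has_l = bounds.lower is not None
    has_u = bounds.upper is not None
    if has_l and has_u:
        return Boundedness.DOUBLE
    if has_l:
        return Boundedness.LOWER
    if has_u:
        return Boundedness.UPPER
    return Boundedness.UNBOUNDED


def standardize(v: float, bounds: BoundsSpec) -> float:
    """Map an observation to the standard scale of its model family.

    double -> (v-L)/(U-L); lower -> v-L; upper -> U-v; unbounded -> v.
    """
    v_arr = np.asarray(v, dtype=float)
    lo = -math.inf if bounds.lower is None else bounds.lower
    hi = math.inf if bounds.upper is None else bounds.upper
    if np.any(v_arr < lo) or np.any(v_arr > hi):
        raise ValueError(f"value {v} outside declared bounds [{lo}, {hi}]")
    cls = classify_bounds(bounds)
    if cls is Boundedness.DOUBLE:
        out = (v_arr - bounds.lower) / bounds.width
    elif cls is Boundedness.LOWER:
        out = v_arr - bounds.lower
    elif cls is Boundedness.UPPER:
        out = bounds.upper - v_arr
    else:
        out = v_arr
    return float(out) if np.isscalar(v) or out.ndim == 0 else out


def destandardize(x: float, bounds: BoundsSpec) -> float:
    """Inverse of :func:`standardize`."""
    x_arr = np.asarray(x, dtype=float)
    cls = classify_bounds(bounds)
    if cls is Boundedness.DOUBLE:
        out = bounds.lower + x_arr * bounds.width
    elif cls is Boundedness.LOWER:
        out = bounds.lower + x_arr
    elif cls is Boundedness.UPPER:
        out = bounds.upper - x_arr
    else:
        out = x_arr
    return float(out) if np.isscalar(x) or out.ndim == 0 else out


@dataclass(frozen=True)
class BetaSpec:
    """Beta model for a double-bounded variable.

    ``p`` and ``q`` are the standard positive shape parameters; ``bounds``
    carries the general-support information (both bounds finite).
    """

    p: float
    q: float
    bounds: BoundsSpec = BoundsSpec(0.0, 1.0)

    def __post_init__(self) -> None:
        if not (self.p > 0 and self.q > 0):
            raise ValueError(f"beta shapes must be positive, got p={self.p}, q={self.q}")
        if classify_bounds(self.bounds) is not Boundedness.DOUBLE:
            raise ValueError("BetaSpec requires both bounds present")


@dataclass(frozen=True)
class GammaSpec:
    """Gamma model for a single-bounded variable.

    ``dispersion`` is the scale parameter delta_L (or delta_U for the
    flipped, upper-bounded orientation), in the variable's units.  The
    orientation follows from which bound is declared.
    """

    k: float
    dispersion: float
    bounds: BoundsSpec = BoundsSpec(lower=0.0)

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError(f"gamma shape must be positive, got k={self.k}")
        if not self.dispersion > 0:
            raise ValueError(f"gamma dispersion must be positive, got {self.dispersion}")
        if classify_bounds(self.bounds) not in (Boundedness.LOWER, Boundedness.UPPER):
            raise ValueError("GammaSpec requires exactly one bound present")

    @property
    def flipped(self) -> bool:
        """True for the upper-bounded (reflected) orientation."""
        return classify_bounds(self.bounds) is Boundedness.UPPER


@dataclass(frozen=True)
class MeanDispersion:
    """A (mean, delta) parameter point on the raw (general) scale.

    ``delta`` is dimensionless for double-bounded variables, in the
    variable's units for single-bounded ones, and in squared units
    (the variance) for unbounded ones.
    """

    mean: float
    delta: float


DistSpec = Union[BetaSpec, GammaSpec]


def _standard_mean(mean: float, bounds: BoundsSpec) -> float:
    """Standardized mean, rejecting means at/outside the bounds."""
    lo = -math.inf if bounds.lower is None else bounds.lower
    hi = math.inf if bounds.upper is None else bounds.upper
    if bounds.lower is not None and mean - lo <= BOUND_TOL * max(1.0, abs(lo)):
        raise ValueError(f"mean {mean} at or below the lower bound {lo}")
    if bounds.upper is not None and hi - mean <= BOUND_TOL * max(1.0, abs(hi)):
        raise ValueError(f"mean {mean} at or above the upper bound {hi}")
    return standardize(mean, bounds)


def beta_from_mean_dispersion(md: MeanDispersion, bounds: BoundsSpec) -> BetaSpec:
    """Beta shapes from (mean, delta2): p = mu(1/delta2 - 1), q = (1-mu)(1/delta2 - 1)."""
    if classify_bounds(bounds) is not Boundedness.DOUBLE:
        raise ValueError("the beta family requires both bounds")
    mu = _standard_mean(md.mean, bounds)
    if not 0.0 < md.delta < 1.0:
        raise ValueError(f"delta2 must lie in (0, 1), got {md.delta}")
    conc = 1.0 / md.delta - 1.0  # p + q
    return BetaSpec(p=mu * conc, q=(1.0 - mu) * conc, bounds=bounds)


def beta_moments(spec: BetaSpec) -> tuple[float, float, float]:
    """Standard-scale (mean, variance, delta2) of a beta spec.

    mu = p/(p+q); sigma^2 = pq / [(p+q)^2 (1+p+q)]; delta2 = 1/(1+p+q),
    which equals sigma^2 / [mu (1-mu)] — the mean-independence identity.
    """
    p, q = spec.p, spec.q
    s = p + q
    mu = p / s
    var = p * q / (s * s * (1.0 + s))
    delta2 = 1.0 / (1.0 + s)
    return mu, var, delta2


def gamma_from_mean_dispersion(md: MeanDispersion, bounds: BoundsSpec) -> GammaSpec:
    """Gamma shape from (mean, delta_L): k = mu / delta_L on the standard scale."""
    if classify_bounds(bounds) not in (Boundedness.LOWER, Boundedness.UPPER):
        raise ValueError("the gamma family requires exactly one bound")
    if not md.delta > 0:
        raise ValueError(f"dispersion must be positive, got {md.delta}")
    mu = _standard_mean(md.mean, bounds)
    if not mu > 0:
        raise ValueError(f"standardized mean must be positive, got {mu}")
    return GammaSpec(k=mu / md.delta, dispersion=md.delta, bounds=bounds)


def gamma_moments(spec: GammaSpec) -> tuple[float, float]:
    """Standard-scale (mean, variance): mu = k*delta, sigma^2 = mu*delta."""
    mu = spec.k * spec.dispersion
    return mu, mu * spec.dispersion


def general_moments(spec: DistSpec) -> tuple[float, float]:
    """(mean, variance) on the raw (general) scale of the spec's bounds."""
    if isinstance(spec, BetaSpec):
        mu, var, _ = beta_moments(spec)
        w = spec.bounds.width
        return destandardize(mu, spec.bounds), var * w * w
    mu, var = gamma_moments(spec)
    return destandardize(mu, spec.bounds), var


def mean_dispersion_of(spec: DistSpec) -> MeanDispersion:
    """The (mean, delta) point a spec represents, mean on the raw scale."""
    if isinstance(spec, BetaSpec):
        mu, _, d2 = beta_moments(spec)
        return MeanDispersion(mean=destandardize(mu, spec.bounds), delta=d2)
    mu, _ = gamma_moments(spec)
    return MeanDispersion(mean=destandardize(mu, spec.bounds), delta=spec.dispersion)


def pdf(spec: DistSpec, v):
    """Density at raw value(s) ``v``; 0 outside the support.

    The general density is the standard one at the standardized value,
    divided by the Jacobian (U - L for beta; 1 for gamma shifts/flips).
    For beta shapes with p < 1 or q < 1 the density diverges at the
    corresponding support edge and +inf is returned there.
    """
    v_arr = np.asarray(v, dtype=float)
    scalar = v_arr.ndim == 0
    v_arr = np.atleast_1d(v_arr)
    out = np.zeros_like(v_arr)
    if isinstance(spec, BetaSpec):
        L, U = spec.bounds.lower, spec.bounds.upper
        inside = (v_arr >= L) & (v_arr <= U)
        x = (v_arr[inside] - L) / (U - L)
        out[inside] = _beta_pdf_standard(x, spec.p, spec.q) / (U - L)
    else:
        if spec.flipped:
            inside = v_arr <= spec.bounds.upper
            x = spec.bounds.upper - v_arr[inside]
        else:
            inside = v_arr >= spec.bounds.lower
            x = v_arr[inside] - spec.bounds.lower
        out[inside] = _gamma_pdf_standard(x, spec.k, spec.dispersion)
    return float(out[0]) if scalar else out


def _beta_pdf_standard(x, p, q):
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        logpdf = (
            special.xlogy(p - 1.0, x)
            + special.xlog1py(q - 1.0, -x)
            - special.betaln(p, q)
        )
        out = np.exp(logpdf)
    # edge conventions: x^(p-1) at x=0 is inf for p<1, 1 for p=1, 0 for p>1
    if p < 1:
        out = np.where(x == 0.0, np.inf, out)
    if q < 1:
        out = np.where(x == 1.0, np.inf, out)
    return out


def _gamma_pdf_standard(x, k, scale):
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        logpdf = (
            special.xlogy(k - 1.0, x)
            - x / scale
            - special.gammaln(k)
            - k * math.log(scale)
        )
        out = np.exp(logpdf)
    if k < 1:
        out = np.where(x == 0.0, np.inf, out)
    return out


def cdf(spec: DistSpec, v):
    """Distribution function at raw value(s) ``v``.

    Beta uses the regularized incomplete beta function; gamma the
    regularized lower incomplete gamma.  The flipped gamma satisfies
    F(v) = 1 - F_standard(U - v).
    """
    v_arr = np.asarray(v, dtype=float)
    scalar = v_arr.ndim == 0
    v_arr = np.atleast_1d(v_arr)
    if isinstance(spec, BetaSpec):
        L, U = spec.bounds.lower, spec.bounds.upper
        x = np.clip((v_arr - L) / (U - L), 0.0, 1.0)
        out = special.betainc(spec.p, spec.q, x)
    elif spec.flipped:
        x = np.maximum(spec.bounds.upper - v_arr, 0.0)
        out = 1.0 - special.gammainc(spec.k, x / spec.dispersion)
    else:
        x = np.maximum(v_arr - spec.bounds.lower, 0.0)
        out = special.gammainc(spec.k, x / spec.dispersion)
    return float(out[0]) if scalar else out


def dist_mode(spec: DistSpec) -> float:
    """Mode on the raw scale; used to seed the Newton quantile solver.

    Gamma: (k-1)*delta for k >= 1, else 0 (mass piles at the bound).
    Beta: (p-1)/(p+q-2) when both shapes exceed 1; otherwise the nearer
    support edge, nudged inward by 1e-9*(U-L) so the seed stays in the
    open support (symmetric edge cases use the centre).
    """
    if isinstance(spec, GammaSpec):
        x_mode = (spec.k - 1.0) * spec.dispersion if spec.k >= 1.0 else 0.0
        return destandardize(x_mode, spec.bounds)
    p, q = spec.p, spec.q
    if p > 1.0 and q > 1.0:
        x_mode = (p - 1.0) / (p + q - 2.0)
    elif p == q:
        x_mode = 0.5
    elif p < q:
        x_mode = 1e-9
    else:
        x_mode = 1.0 - 1e-9
    return destandardize(x_mode, spec.bounds)
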