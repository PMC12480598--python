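# Methods

## Model families and the (mean, δ) parameterization

A double-bounded variable on [L, U] is modelled by the beta
distribution after the affine standardization x = (v − L)/(U − L); a
single-bounded variable by the gamma distribution after x = v − L
(lower bound) or x = U − v (upper bound; a reflected gamma, so the
bound plays the role of the gamma's zero).  Unbounded variables default
to the normal model, for which the dispersion is the variance itself;
no normal density machinery is exposed because δ is the only quantity
defined there.

Both bounded families are reparameterized by (μ, δ):

* beta: μ = p/(p+q), δ₂ = 1/(1+p+q), with inverse p = μ(1/δ₂ − 1),
  q = (1−μ)(1/δ₂ − 1).  σ² = δ₂·μ(1−μ), so δ₂ = σ²/[μ(1−μ)] — the
  variance with its mean-dependence divided out.
* gamma: μ = kδ_L, σ² = μδ_L, so δ_L = σ²/μ, k = μ/δ_L.

δ₂ is dimensionless and lies in (0, 1); δ_L/δ_U carry the variable's
units; δ₀ = σ² carries squared units.  δ is therefore not
scale-invariant for single-bounded and unbounded variables — samples
must share units before their δ values are compared.

Degenerate inputs: a sample (or parameter) mean lying within 1e-12 of
a declared bound is rejected rather than clamped, because δ's
denominator vanishes there; a zero-variance sample has δ = 0 whatever
the mean.  Bounds must be declared conceptually or experimentally —
using the observed sample min/max as bounds would make δ̂ circular.

## Closed-form measures and the quantile solver

CV, Gini and skewness are computed on the standardized variable (both
are changed by location shifts, so only the standard form is
meaningful); sd, variance and the 0.95 quantile range are reported in
raw units; differential entropy gains the change-of-variables term
ln(U − L) for general double-bounded variables and nothing for pure
shifts or reflections.  The ln(U − L) adjustment is implied by the
change of variables rather than being part of the standard-form
derivations, and is called out here for that reason.

Gini and entropy closed forms are evaluated in log-gamma/digamma space
(`scipy.special.betaln/gammaln/digamma`), so shape parameters in the
1e5–1e6 range do not overflow.

The 0.95 quantile range solves F(x) = 0.025 and 0.975 with Newton's
method seeded at the distribution mode, tolerance 1e-12, at most 100
iterations, steps clamped into the open support by halving toward the
violated edge.  Elements that fail to converge fall back to Brent
bisection bracketed by the support edges (the gamma upper bracket is
expanded by doubling).  The solver is vectorized over parameter
arrays, which is what keeps the 500×500 warp grid near-instant.  When
the beta has no interior mode (p ≤ 1 or q ≤ 1) the Newton seed is the
nearer support edge nudged inward by 1e-9 (centre for symmetric
cases); the seed only needs to be inside the open support.  Where a
density diverges at a support edge (beta with p < 1 or q < 1, gamma
with k < 1) the pdf returns +inf at the edge; the cdf is unaffected.

## Estimators

* Variance convention: denominator n−1 by default (configurable to n).
  At the default tile size of 400 the difference is below 0.3 %, but
  the convention is pinned for reproducibility.
* Empirical quantiles: linear interpolation between order statistics
  (numpy's default).  Both the 0.025–0.975 quantile range and the
  min–max range are available, because published elevation-range
  covariates use the min–max convention while the distributional range
  is the 0.95 quantile extent; min–max is the convention intended for
  the empirical model suite's ρ.
* Gini: half the relative mean absolute difference over all ordered
  pairs including i = j (denominator 2n²μ), computed via the sorted
  cumulative form in O(n log n); the brute-force double loop serves as
  the test oracle.
* Differential entropy: the Kozachenko–Leonenko k-nearest-neighbour
  estimator (default k = 3) in nats; exact-duplicate distances are
  floored at machine-epsilon scale before the log.  The banded Shannon
  entropy over user-chosen band edges is provided as the classical
  foliage-height-diversity analogue; its dependence on the band choice
  is precisely why the kNN estimator is preferred.

## Bias testing

Tiles are mean-balanced by two-phase stratified resampling: optional
filters first (a per-tile valid-area fraction threshold, default 0.75,
generalizing a land-fraction filter; an optional mean cap emulating
the removal of extreme-mean tiles), then evenly spaced mean strata and
up to a fixed number of tiles per stratum, sampled without replacement
when the stratum is large enough and with replacement when short.

The analytic bias models predict each measure from the tile mean and
the across-tile average δ̂: s = √(δ̄·g), s² = δ̄·g, CV = √(δ̃·g)/x̄,
with g = (x̄−L), (x̄−L)(U−x̄) or (U−x̄) per boundedness class.  The
mean of δ̂ drives the sd and variance predictions; the median drives
the CV, whose prediction diverges at small means and is therefore
sensitive to heavy-tailed δ̂ values.  The null model predicts every
tile with the across-tile mean of the observed measure.  The two are
compared by a two-sided paired t-test on per-tile squared errors
(df = n−1).

δ's mean-independence is established by equivalence testing (TOST at
α = 0.05; the α is pinned here and configurable, since only the test
family is prescribed by the framework).  δ̂ and the reference measure
are min–max rescaled to [0, 1], both are regressed on the mean-derived
predictor of the reference measure's model form (the bias model with
the δ factor removed), and two one-sided t-tests ask whether δ's
coefficient lies within ± half the absolute reference coefficient.

## Warp grid and the model suite

The theoretical richness surface is

    D = 66.395 + 3.034e-2·μ − 1.188e-5·μ² + 1.076e-1·δ

an intercept, a hump-shaped mean relationship and a monotonic positive
dispersion relationship, with no δ² term.  The warp grid crosses
uniformly spaced μ (default 64–2422) with uniformly spaced δ (default
0.64–144.0) assuming the gamma family with L = 0 (family and bounds
configurable), evaluates D and every analytic measure at each point,
and fits a second-degree polynomial of D on each measure (measure
min–max rescaled; the quadratic coefficient's sign is invariant to
that).  Because μ and δ are independent on the grid and D is linear in
δ, the δ-based quadratic coefficient is zero up to numerics, while the
range-, sd- and cv-based fits acquire nonzero quadratic terms — the
artifact mechanism.  The default polynomial-fitting grid is 500×500;
a smaller grid (50×50) gives the same signs and is used where speed
matters.

The model suite fits five OLS models of richness on combinations of
the rescaled mean (μ, μ²), range-based heterogeneity (ρ, ρ²) and δ
(δ, δ²): #1 ρ-only, #2 mean + ρ, #3 δ-only, #4 mean + δ + δ², #5
mean + δ.  Predictors are min–max rescaled to [0, 1] *after* any
filtering, using the filtered sample's min/max (the ordering is pinned
here; either choice only reparameterizes the coefficients, and the
stored scaling constants let coefficients be mapped back to raw
units).  Quadratic terms are squares of the rescaled base predictor.
Each fit records the intercept-only F-test; nested models are compared
with the standard extra-sum-of-squares F; the #4-vs-#5 comparison has
one extra term, so the numerator df reported is 1 (n − 5 in the
denominator).

## Synthetic data

`gen_tiles` draws fixed-size tiles (default 400 pixels per tile,
matching the tile size of the large-scale elevation/crop-cover
analyses) from the gamma or beta family at per-tile means and a shared
or per-tile δ.  The default bias-testing condition is 200 gamma tiles
with δ_L = 2 and means uniform on [10, 400]: wide enough to span two
orders of magnitude of shape parameter (k = 5 to 200) so every
mean-biased measure shows its trend, while keeping k ≥ 5 so tiles stay
well inside gamma territory.  One integer seed expands through
`numpy.random.SeedSequence` into per-tile substreams, so growing the
tile count never reshuffles earlier tiles; truth tables (generating μ
and δ per tile) always accompany the observations, and tests compare
estimates to truth, never to other estimates.

`gen_richness_survey` is a synthetic stand-in for a gridded richness
survey: n = 285 cells by default, μ and δ uniform over the warp-grid
ranges, D = surface + N(0, sd 5) noise (the theoretical surface itself
is noise-free; the additive Gaussian noise and its sd are this
package's choice of a plausible survey error), ρ the analytic 0.95
quantile range of the implied gamma distribution, and a unit coverage
column so the border-cell filter can be exercised.

What the generators do *not* emulate: spatial autocorrelation between
tiles or cells, raster void-filling or classification error,
non-gamma/beta tails, and sampling-effort gradients.  Passing tests
therefore show that the estimators and tests behave correctly when the
distributional assumptions hold; they do not by themselves validate
the measure on any particular real raster.

## Numerical and design notes

* The coefficient-recovery study checks each model-#5 coefficient
  against its generating value (mapped onto the rescaled predictor
  scale) within 2 standard errors, per coefficient across replicates.
  Per-coefficient coverage is the quantity with the nominal ~95 %
  rate; the joint event "all four coefficients simultaneously within
  2 SE" runs near 88 % because the estimates are correlated, and is
  reported separately by the acceptance script.
* Paired t-tests with exactly tied inputs report t = 0, p = 1 with a
  tie flag; zero-variance nonzero differences report an infinite-t
  sentinel.
* JSON reports serialize floats via Python's shortest-round-trip repr,
  so written values re-read exactly.
* Problem sizes used by the test suite and acceptance script: 200k
  draws per Monte-Carlo oracle point, 200 tiles × 400 pixels for the
  mean-independence and bias-model studies, the 500×500 warp grid, and
  100 recovery replicates at n = 285 — sizes chosen so each study's
  statistical power is ample at desk scale.

## Limitations

δ is derived for variables adequately modelled by beta/gamma/normal
families; heavily multimodal or discrete variables are out of scope,
as is maximum-likelihood fitting of the families themselves.  δ
disentangles *dispersion* from the mean; entropy- and
inequality-flavoured characteristics of heterogeneity remain
mean-entangled and are reported only as the biased measures they are.
Single-bounded and unbounded δ are unit-dependent (see above).  The
empirical Catalonia benchmark requires externally retrieved survey and
elevation data and is not shipped.
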