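# deltadisp

Mean-independent statistical dispersion (δ) for bounded continuous
variables, together with the analytic and empirical machinery needed to
show why the usual heterogeneity measures are biased by the mean — and
what that bias does to heterogeneity–diversity regressions in ecology.

## The problem

Variance, standard deviation, CV, Gini coefficient, differential
entropy and the 0.95 quantile range are all routinely used to quantify
the heterogeneity of a continuous variable (land elevation, vegetation
cover, foliage height, wealth, …).  When the variable has a lower
and/or upper bound, none of these measures is independent of the mean:
as the mean approaches a bound, the distribution is forced to
concentrate there, and every one of those measures moves even when the
underlying dispersion is unchanged.  Any downstream regression of a
response (say, species richness *D*) on such a measure inherits the
mean–response relationship as an artifact — hump-shaped
heterogeneity–diversity relationships can appear out of a purely linear
heterogeneity effect.

## The measure

For a variable with declared lower bound *L* and/or upper bound *U*,
the mean-independent dispersion is the variance normalized by the
mean's distance(s) to the bound(s):

```
δ = σ² / [(μ − L)^𝟙(L) · (U − μ)^𝟙(U)]
```

where the indicator exponent 𝟙(·) is 1 when the bound is a real number
and 0 otherwise.  The special cases:

| bounds        | model family  | δ                          |
|---------------|---------------|----------------------------|
| double (L, U) | beta          | δ₂ = σ²/[(μ−L)(U−μ)] = 1/(1+p+q) |
| lower (L)     | gamma         | δ_L = σ²/(μ−L) = scale     |
| upper (U)     | flipped gamma | δ_U = σ²/(U−μ)             |
| none          | normal        | δ₀ = σ²                    |

For beta- and gamma-distributed variables δ recovers the
distribution's dispersion parameter exactly, so at fixed δ a change in
the mean moves the distribution without changing its dispersion —
which is what "mean-independent" means here, and what the package
demonstrates both analytically and on simulated samples.

## Worked example

Per-tile heterogeneity profiles for 200 simulated elevation-like tiles
(gamma family, dispersion fixed at δ_L = 2, tile means spread over
10–400 m), then a regression of each measure on the tile mean:

```python
import statsmodels.api as sm
from deltadisp import BoundsSpec, TileSetConfig, gen_tiles, profile_table

bounds = BoundsSpec(lower=0.0)
obs, truth = gen_tiles(TileSetConfig(
    family="gamma", bounds=bounds, means=(10.0, 400.0), delta=2.0,
    n_tiles=200, tile_size=400, seed=1))
tiles = profile_table(obs, "tile", "value", bounds)

for col in ("delta", "variance", "sd", "cv"):
    t = sm.OLS(tiles[col], sm.add_constant(tiles["mean"])).fit().tvalues.iloc[1]
    print(f"{col:9s} slope-t vs mean: {t:8.1f}")
```

Output:

```
delta     slope-t vs mean:     -1.4
variance  slope-t vs mean:     90.1
sd        slope-t vs mean:     66.1
cv        slope-t vs mean:    -20.0
```

Variance, sd and CV show overwhelming mean trends even though the
generating dispersion is identical for every tile; δ̂ shows none
(|t| < 2).  The same pipeline is available from the shell:

```
deltadisp delta --input obs.csv --group-col tile --value-col value \
    --lower 0 --out profiles.csv
deltadisp bias-curves --family gamma --lower 0 --delta 2 \
    --mean-grid 10:400:100 --out curves.csv
deltadisp bias-test --profiles profiles.csv --lower 0 --out report.json
deltadisp simulate-hdr --grid 500 --out warp.csv
deltadisp fit-hdr --cells cells.csv --models 1,2,3,4,5 --out fits.json
```

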