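"""Seeded generators for tile samples and richness surveys.

``gen_tiles`` emulates the raster tiling behind the empirical bias
tests: each tile is a fixed-size sample (default 400 pixels, the tile
size of the elevation/crop-cover analysis) drawn from a gamma
(elevation-like, lower-bounded) or beta (cover-like, double-bounded)
distribution at a tile-specific mean and a shared or tile-specific
dispersion.  ``gen_richness_survey`` produces synthetic richness
surveys on the theoretical richness surface with additive Gaussian
noise, including the range-based heterogeneity measure (rho) implied by
the gamma model so mean-biased regressions can be exercised.

Seeding: one integer seed expands through ``numpy.random.SeedSequence``
into per-tile substreams, so increasing the tile count never reshuffles
earlier tiles.  Truth tables (the generating mu and delta per unit) are
always returned alongside the observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
import pandas as pd

from . import analytic_measures as am
from .distributions import (
    Boundedness,
    BoundsSpec,
    classify_bounds,
)
from .hdr_analysis import CATALONIA_RICHNESS, RichnessModelSpec, richness_truth

__all__ = ["TileSetConfig", "gen_tiles", "gen_richness_survey"]


@dataclass(frozen=True)
class TileSetConfig:
    """Configuration for a synthetic tile set.

    ``means`` is either a (low, high) range sampled uniformly or an
    explicit per-tile list; ``delta`` a single shared value or a
    per-tile list.  Dispersion is delta2 (dimensionless, in (0,1)) for
    the beta family and delta_L/delta_U (variable units) for gamma.
    """

    family: str
    bounds: BoundsSpec
    means: Union[tuple[float, float], Sequence[float]]
    delta: Union[float, Sequence[float]]
    n_tiles: int
    tile_size: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("gamma", "beta"):
            raise ValueError(f"family must be 'gamma' or 'beta', got {self.family!r}")
        if self.tile_size < 2:
            raise ValueError("tile_size must be >= 2")
        if self.n_tiles < 1:
            raise ValueError("n_tiles must be >= 1")
        cls = classify_bounds(self.bounds)
        if self.family == "beta" and cls is not Boundedness.DOUBLE:
            raise ValueError("beta family requires both bounds")
        if self.family == "gamma" and cls not in (Boundedness.LOWER, Boundedness.UPPER):
            raise ValueError("gamma family requires exactly one bound")


def _resolve_means_deltas(config: TileSetConfig, rng: np.random.Generator):
    if isinstance(config.means, tuple) and len(config.means) == 2 and \
            np.isscalar(config.means[0]):
        mus = rng.uniform(config.means[0], config.means[1], size=config.n_tiles)
    else:
        mus = np.asarray(config.means, dtype=float)
        if mus.size != config.n_tiles:
            raise ValueError("explicit means list must have n_tiles entries")
    if np.isscalar(config.delta):
        deltas = np.full(config.n_tiles, float(config.delta))
    else:
        deltas = np.asarray(config.delta, dtype=float)
        if deltas.size != config.n_tiles:
            raise ValueError("explicit delta list must have n_tiles entries")
    return mus, deltas


def _check_feasible(config: TileSetConfig, mus: np.ndarray, deltas: np.ndarray) -> None:
    b = config.bounds
    lo = -np.inf if b.lower is None else b.lower
    hi = np.inf if b.upper is None else b.upper
    if np.any((mus <= lo) | (mus >= hi)):
        raise ValueError("tile means must lie strictly inside the bounds")
    if np.any(deltas <= 0):
        raise ValueError("delta must be positive")
    if config.family == "beta" and np.any(deltas >= 1):
        raise ValueError("beta dispersion delta2 must be < 1")


def gen_tiles(config: TileSetConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a tile set; returns (observations, truth).

    Observations: one row per pixel, columns (tile, value).  Truth: one
    row per tile, columns (tile, mu, delta).  Reruns with the same
    config are byte-identical; each tile owns an independent substream
    spawned from the seed.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_tiles + 1)
    mean_rng = np.random.default_rng(children[0])
    mus, deltas = _resolve_means_deltas(config, mean_rng)
    _check_feasible(config, mus, deltas)

    b = config.bounds
    values = np.empty((config.n_tiles, config.tile_size))
    for i in range(config.n_tiles):
        rng = np.random.default_rng(children[i + 1])
        if config.family == "gamma":
            if classify_bounds(b) is Boundedness.LOWER:
                mu_std = mus[i] - b.lower
                x = rng.gamma(shape=mu_std / deltas[i], scale=deltas[i],
                              size=config.tile_size)
                values[i] = b.lower + x
            else:
                mu_std = b.upper - mus[i]
                x = rng.gamma(shape=mu_std / deltas[i], scale=deltas[i],
                              size=config.tile_size)
                values[i] = b.upper - x
        else:
            w = b.width
            mu_std = (mus[i] - b.lower) / w
            conc = 1.0 / deltas[i] - 1.0
            x = rng.beta(mu_std * conc, (1.0 - mu_std) * conc, size=config.tile_size)
            values[i] = b.lower + x * w
    tile_ids = np.repeat(np.arange(config.n_tiles), config.tile_size)
    obs = pd.DataFrame({"tile": tile_ids, "value": values.ravel()})
    truth = pd.DataFrame({"tile": np.arange(config.n_tiles), "mu": mus, "delta": deltas})
    return obs, truth


def gen_richness_survey(
    n_cells: int = 285,
    mu_range: tuple[float, float] = (64.0, 2422.0),
    delta_range: tuple[float, float] = (0.64, 144.0),
    spec: RichnessModelSpec = CATALONIA_RICHNESS,
    noise_sd: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic richness survey on the theoretical richness surface.

    Cell means and dispersions are uniform over their ranges; richness
    is the deterministic surface plus N(0, noise_sd) noise.  The cell
    table also carries rho, the analytic 0.95 quantile range of the
    implied gamma distribution, so mean-biased regressions can be fit,
    and a unit coverage column for the border filter.  This is a
    synthetic stand-in for a real bird-atlas survey: defaults match the
    study scale (285 interior cells, richness noise sd 5).
    """
    if n_cells < 10:
        raise ValueError("need at least 10 cells")
    rng = np.random.default_rng(seed)
    mu = rng.uniform(mu_range[0], mu_range[1], size=n_cells)
    delta = rng.uniform(delta_range[0], delta_range[1], size=n_cells)
    D = richness_truth(mu, delta, spec) + rng.normal(0.0, noise_sd, size=n_cells)
    k = mu / delta
    rho = am._gamma_qrange95(k, delta)
    return pd.DataFrame({
        "cell": np.arange(n_cells),
        "D": D,
        "mu": mu,
        "delta": delta,
        "rho": rho,
        "coverage": np.ones(n_cells),
    })
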