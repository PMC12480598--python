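import numpy as np
import pytest

from deltadisp.distributions import BoundsSpec
from deltadisp.sample_measures import profile_table
from deltadisp.synthetic_data import TileSetConfig, gen_tiles

LOWER = BoundsSpec(lower=0.0)
UNIT = BoundsSpec(0.0, 1.0)
PERCENT = BoundsSpec(0.0, 100.0)


@pytest.fixture(scope="session")
def gamma_tiles():
    """200 elevation-like gamma tiles (n=400 each), dispersion fixed at 2,
    tile means spread uniformly over [10, 400]; profiles attached."""
    config = TileSetConfig(
        family="gamma", bounds=LOWER, means=(10.0, 400.0), delta=2.0,
        n_tiles=200, tile_size=400, seed=1,
    )
    obs, truth = gen_tiles(config)
    tiles = profile_table(obs, "tile", "value", LOWER)
    return tiles, truth


@pytest.fixture(scope="session")
def beta_tiles():
    """Crop-cover-like beta tiles on [0, 100] with delta2 fixed at 0.1."""
    config = TileSetConfig(
        family="beta", bounds=PERCENT, means=(5.0, 95.0), delta=0.1,
        n_tiles=200, tile_size=400, seed=2,
    )
    obs, truth = gen_tiles(config)
    tiles = profile_table(obs, "tile", "value", PERCENT)
    return tiles, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
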