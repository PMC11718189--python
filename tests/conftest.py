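import pytest

from trophoscale.config import CarnivoreParams, NPPParams, SyntheticConfig
from trophoscale.synthetic import generate_admin_layout, generate_world


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Small deterministic world: 2 counties x 2 municipalities on 8x8 cells."""
    return SyntheticConfig(
        seed=11,
        n_counties=2,
        municipalities_per_county=2,
        grid_shape=(8, 8),
        cell_area=0.25,
        years=(1990, 2015),
        census_years=(1999, 2009, 2015),
        land_cover_fractions=(0.6, 0.4, 0.0),
        npp_params=NPPParams(base=300_000.0, gradient=0.0, forest_multiplier=1.0,
                             open_multiplier=1.0, noise_sd=0.0),
        carnivore_params=(
            CarnivoreParams("wolf", 1.2, 1 / 6, 100.0),
            CarnivoreParams("lynx", 1.1, 0.05, 60.0),
        ),
        deterministic=True,
        livestock_means={"sheep": 1000.0, "cattle": 50.0},
        wild_density_means={"moose": 40.0, "wild reindeer": 10.0},
    )


@pytest.fixture(scope="session")
def small_layout(small_config):
    return generate_admin_layout(small_config)


@pytest.fixture(scope="session")
def small_world(small_config):
    return generate_world(small_config)
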