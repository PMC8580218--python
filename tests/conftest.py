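import numpy as np
import pytest

from wastewater.factors import FIOWeights, RemovalRates
from wastewater.synth import WorldConfig, generate_world


@pytest.fixture(scope="session")
def small_world():
    """48x48 single-island world with some table missingness."""
    cfg = WorldConfig(
        grid_rows=48,
        grid_cols=48,
        n_countries=4,
        population_total=200_000,
        sanitation_strata_missing=0.25,
        protein_missing=0.25,
        gdp_missing=0.4,
        rng_seed=3,
    )
    return generate_world(cfg)


@pytest.fixture
def default_rates():
    return RemovalRates()


@pytest.fixture
def default_weights():
    return FIOWeights()


def ring_island(rows, cols):
    """Land everywhere except a 1-cell ocean border."""
    land = np.zeros((rows, cols), dtype=bool)
    land[1:-1, 1:-1] = True
    return land
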