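import numpy as np
import pandas as pd
import pytest

from mpameta.synthetic import (
    SimConfig,
    generate_network,
    generate_species_pool,
    simulate_surveys,
    species_to_frame,
)


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    """A small but fully structured simulated monitoring program."""
    return SimConfig(
        n_mpas=12,
        n_species=8,
        years=(2018, 2019),
        ecosystem_coverage=0.8,
        seed=7,
    )


@pytest.fixture(scope="session")
def species_pool(tiny_config):
    return generate_species_pool(tiny_config.n_species, tiny_config.seed)


@pytest.fixture(scope="session")
def species_frame(species_pool):
    return species_to_frame(species_pool)


@pytest.fixture(scope="session")
def network(tiny_config):
    return generate_network(tiny_config)


@pytest.fixture(scope="session")
def surveys(network, species_pool, tiny_config):
    return simulate_surveys(network, species_pool, tiny_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


def toy_effects_table() -> pd.DataFrame:
    """Four effects in two regions, two ecosystems; single status/protection."""
    return pd.DataFrame(
        {
            "mpa_id": ["m1", "m1", "m2", "m3"],
            "ecosystem": ["kelp_forest", "deep_reef", "kelp_forest", "deep_reef"],
            "region": ["north", "north", "south", "south"],
            "year": [2019] * 4,
            "status": ["targeted"] * 4,
            "protection": ["no_take"] * 4,
            "Y": [0.5, 0.2, -0.1, 0.8],
            "v": [0.05, 0.1, 0.2, 0.05],
        }
    )
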