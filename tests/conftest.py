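import numpy as np
import pytest

from adoptnet import (
    KernelParams,
    allocate_agents,
    build_spatial_network,
    generate_synthetic_cities,
)


@pytest.fixture(scope="session")
def small_table():
    """Ten synthetic cities, fixed seed."""
    return generate_synthetic_cities(10, seed=42)


@pytest.fixture(scope="session")
def small_pop(small_table):
    return allocate_agents(small_table, 2_000)


@pytest.fixture(scope="session")
def small_spatial_net(small_table, small_pop):
    return build_spatial_network(
        small_pop, small_table, 8.0, KernelParams(homophily_pref=0.7), seed=7
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
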