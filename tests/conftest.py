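import numpy as np
import pytest

from gwlasso import SimulationConfig, generate_dataset, pairwise_distances


@pytest.fixture(scope="session")
def default_data():
    """The desk-scale study conditions used across the suite (N=200, p=10)."""
    config = SimulationConfig()
    dataset, truth = generate_dataset(config)
    return config, dataset, truth


@pytest.fixture(scope="session")
def default_distances(default_data):
    _, dataset, _ = default_data
    return pairwise_distances(dataset.coords).D


@pytest.fixture(scope="session")
def small_data():
    """A quicker N=60, p=4 dataset for unit tests."""
    config = SimulationConfig(n=60, p=4, n_active=2, surface_lengthscale=3.0,
                              effect_scale=1.5, seed=7)
    dataset, truth = generate_dataset(config)
    return config, dataset, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
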