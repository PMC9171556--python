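import numpy as np
import pytest

from acelink.presets import load_preset, simulate_pairs_preset


@pytest.fixture(scope="session")
def twin_preset():
    return load_preset("catss-twin")


@pytest.fixture(scope="session")
def liability_preset():
    return load_preset("population-liability")


@pytest.fixture(scope="session")
def registry_preset():
    return load_preset("population-registry")


@pytest.fixture(scope="session")
def twin_pairs(twin_preset):
    """One simulated twin cohort at preset scale, reused across tests."""
    return simulate_pairs_preset(twin_preset, seed=1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
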