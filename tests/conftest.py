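import numpy as np
import pytest

from becc import SyntheticConfig, generate_compendium, synthetic_annotation


@pytest.fixture(scope="session")
def small_config():
    """A small planted compendium: fast enough for per-module tests."""
    return SyntheticConfig(
        n_samples=300, n_universal=8, n_subset=4, n_noise=150, rng_seed=0
    )


@pytest.fixture(scope="session")
def small_compendium(small_config):
    return generate_compendium(small_config)


@pytest.fixture(scope="session")
def small_annotation(small_config):
    return synthetic_annotation(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240817)
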