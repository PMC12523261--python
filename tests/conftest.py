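import numpy as np
import pytest

from specgrain.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config():
    """Reduced-scale study conditions: 72 samples on a 60-band 980-1684 nm grid."""
    return GeneratorConfig(n_samples=72, n_bands=60, seed=1)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
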