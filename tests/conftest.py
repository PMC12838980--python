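import numpy as np
import pytest

from painattn.synthetic import NuisanceConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """10 subjects x 10 images with default nuisance; shared read-only."""
    records, profiles = generate_dataset(10, 10, master_seed=123)
    return records, profiles


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free renders for separability / mask diagnostics."""
    records, profiles = generate_dataset(10, 10, master_seed=7,
                                         nuisance=NuisanceConfig.none())
    return records, profiles


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
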