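import numpy as np
import pytest

from mtscompare import SyntheticSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """12 participants x 3 regions x 150 timepoints, no group effect."""
    return generate_dataset(
        SyntheticSpec(n_case=6, n_control=6, n_regions=3, seed=7)
    )
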