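import numpy as np
import pytest

from imco import SyntheticConfig, generate_pairs


@pytest.fixture(scope="session")
def default_pairs():
    """Pairs drawn at the generator's default study conditions."""
    pairs, truth = generate_pairs(SyntheticConfig(seed=11))
    return pairs, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
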