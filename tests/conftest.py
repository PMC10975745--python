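import numpy as np
import pytest

from nirpls import SyntheticConfig, generate


@pytest.fixture(scope="session")
def small_dataset():
    """A compact synthetic dataset shared across read-only tests."""
    return generate(SyntheticConfig(n_samples=60, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
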