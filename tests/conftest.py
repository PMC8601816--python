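import numpy as np
import pytest

from rsdnet import generate, generate_separable, heart_schema


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def heart_table():
    """270 instances from the default heart-like schema."""
    return generate(heart_schema(), 270, seed=1)


@pytest.fixture(scope="session")
def separable_table():
    """Well-separated two-blob problem the network should solve outright."""
    return generate_separable(200, 2, margin=5.0, seed=7)
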