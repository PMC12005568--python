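import numpy as np
import pytest

from mkmg import MKME


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def mkme_sample_100():
    """A fixed simulated MKME(1.2, 0.7) sample of size 100."""
    return MKME(1.2, 0.7).rvs(100, seed=42)
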