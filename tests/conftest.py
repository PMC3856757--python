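import numpy as np
import pytest

from plastisim import GradientSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20130)


@pytest.fixture
def gradient():
    """Default 50-deme gradient."""
    return GradientSpec()


@pytest.fixture
def single_deme_gradient():
    return GradientSpec(n_demes=1)
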