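import numpy as np
import pytest
from hypothesis import settings

from telosas import SimConfig

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def config():
    """Default survivor-clone simulation conditions."""
    return SimConfig()


@pytest.fixture
def quiet_config():
    """Noise-free variant of the default conditions."""
    return SimConfig(od_noise_cv=0.0, ct_noise_sd=0.0, band_position_noise_sd=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
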