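import numpy as np
import pytest

from hemaseg import phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_config():
    """Noise-free, texture-free tiny phantom config (deterministic geometry)."""
    return phantom.PhantomConfig.tiny(noise_sd_hu=0.0, liver_texture_sd_hu=0.0)


@pytest.fixture
def tiny_case(clean_config):
    return phantom.generate_case(clean_config, seed=7)


@pytest.fixture
def noisy_case():
    return phantom.generate_case(phantom.PhantomConfig.tiny(), seed=3)
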