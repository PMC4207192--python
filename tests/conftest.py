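import numpy as np
import pytest

from cpmcassay import DetectionParams, GeneratorConfig


@pytest.fixture
def default_config():
    return GeneratorConfig()


@pytest.fixture
def default_params():
    return DetectionParams()


@pytest.fixture
def quiet_config():
    """Noise-free generator: detector oracle tests need exact traces."""
    return GeneratorConfig(noise_sd=0.0, amplitude_cv=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
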