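import numpy as np
import pytest

from perisr import DisplayModel, ObserverParams


@pytest.fixture(scope="session")
def display() -> DisplayModel:
    return DisplayModel()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def quiet_observer() -> ObserverParams:
    """Noise-free observer for deterministic decision checks."""
    return ObserverParams(blur_sigma=0.0, noise_sd=0.0, fixed_pattern_sd=0.0,
                          strategy="single_frame")
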