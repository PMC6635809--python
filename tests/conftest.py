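import time

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bownet import ModelConfig, make_square_stimulus, run_model

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """Reduced-size configuration for fast integration tests."""
    return ModelConfig(n_levels=4, n_iterations=6)


@pytest.fixture(scope="session")
def square64(small_config):
    """64 px light square stimulus and its full model run."""
    img = make_square_stimulus(64, 24, polarity="light")
    return img, run_model(img, small_config)


@pytest.fixture(scope="session")
def square64_dark(small_config):
    """Contrast inversion of the light square, same geometry."""
    img = make_square_stimulus(64, 24, polarity="dark")
    return img, run_model(img, small_config)


@pytest.fixture(scope="session")
def square128():
    """The timing fixture: 128 px light square, full default configuration.

    Returns (image, output, wall-clock seconds of the run).
    """
    img = make_square_stimulus(128, 48, polarity="light")
    t0 = time.perf_counter()
    out = run_model(img, ModelConfig())
    return img, out, time.perf_counter() - t0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
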