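import numpy as np
import pytest

from burstlapse.containers import Recording
from burstlapse.synth import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240501)


@pytest.fixture
def sine_recording():
    """1 channel, 10 s of a pure 10 Hz sinusoid at 250 Hz."""
    rate = 250.0
    t = np.arange(0, 10, 1 / rate)
    return Recording((40.0 * np.sin(2 * np.pi * 10.0 * t))[None, :], rate, ["CH1"])


@pytest.fixture
def small_config():
    """A short simulated run that still yields a usable trial count."""
    return SimConfig(duration=120.0, n_channels=4, seed=11)
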