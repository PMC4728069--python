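import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import wpdenoise as w

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def white_fixture():
    """A stepped tone at 100% white noise, seeded."""
    return w.noisy_tone_fixture(100.0, seed=7)


@pytest.fixture()
def random_signal(rng):
    return w.AudioSignal(rng.standard_normal(4096), 8000)
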