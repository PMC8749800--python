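import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import imugait as ig

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_trial():
    """Noise-free 10-stride trial with the canonical healthy-gait defaults."""
    return ig.generate_trial(ig.GaitSpec(seed=1))


@pytest.fixture(scope="session")
def noisy_trial():
    """200-stride trial with 5%-of-peak Gaussian noise (Monte-Carlo fixture)."""
    return ig.generate_trial(ig.GaitSpec(seed=7, n_strides=200, noise_sd=0.05))


@pytest.fixture(scope="session")
def noisy_events(noisy_trial):
    signal, _ = noisy_trial
    with np.errstate(all="ignore"):
        return ig.detect_all_events(signal)
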