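import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def grid():
    return np.arange(200.0, 1851.0, 1.0)


@pytest.fixture
def noiseless_truth():
    from ramanfish.synthetic import SyntheticTruth

    return SyntheticTruth(seed=11)


@pytest.fixture
def noisy_truth():
    from ramanfish.synthetic import SyntheticTruth

    return SyntheticTruth(seed=11, noise_sd=1.0)
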