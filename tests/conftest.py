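import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from svrules.synthetic import generate_gaussian

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def separable_dataset():
    """Two well-separated Gaussian clusters (trivial decision boundary)."""
    return generate_gaussian(n=240, d=2, class_means=(0.0, 3.0),
                             class_sd=0.3, imbalance_target=2.0, seed=7)


@pytest.fixture
def overlapping_dataset():
    """Moderately overlapping clusters, both classes well populated."""
    return generate_gaussian(n=300, d=3, class_means=(0.0, 1.2),
                             class_sd=0.8, imbalance_target=2.0, seed=11)
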