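import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import adchist as a

settings.register_profile(
    "default",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config():
    """Reduced grid for geometric-phantom tests; same physics as default."""
    return a.PhantomConfig(grid_shape=(64, 64, 12))


@pytest.fixture(scope="session")
def aging_trajectory():
    """Quadratic decline comparable to normative brain aging."""
    return a.AgeTrajectory(c0=83.5, c1=-0.068, c2=-0.0027, subject_sd=1.5)


@pytest.fixture(scope="session")
def subject_70(small_config):
    sub = a.SubjectGroundTruth("sub-70", 40.0, "female", 70.0, seed=11)
    pair, truth = a.synthesize_with_truth(sub, small_config)
    return sub, pair, truth


def make_histogram(values, b_value=1000.0, edges=None):
    """Percent-normalized histogram straight from raw ADC values."""
    adc_map = a.ADCMap(values=np.asarray(values, dtype=float), b_value=b_value)
    return a.build_histogram(adc_map, edges)
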