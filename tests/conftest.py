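import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_cluster_dataset():
    from tmlevim import ClusterDesign, simulate_cluster

    return simulate_cluster(ClusterDesign(m=2, rho=0.5, sigma_e=5.0, n=150, seed=7))
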