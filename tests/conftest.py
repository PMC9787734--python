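import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_mlr_instance(rng, n=None, p=None):
    """A random full-rank regression instance with mild signal."""
    n = n or int(rng.integers(10, 51))
    p = p or int(rng.integers(1, 6))
    if n <= p + 2:
        n = p + 3
    X = rng.standard_normal((n, p))
    beta = rng.normal(0, 1, p)
    y = X @ beta + rng.standard_normal(n)
    return X, y
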