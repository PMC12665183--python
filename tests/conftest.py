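import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sssiv import IVDataset

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_stratum():
    """Four-point stratum whose weight function is computable by hand.

    Z=(0,0,1,1), X=(1,2,3,4): W has heights (0.25, 0.5, 0.25) on the unit
    intervals (1,2], (2,3], (3,4].
    """
    return IVDataset(z=[0.0, 0.0, 1.0, 1.0], x=[1.0, 2.0, 3.0, 4.0],
                     y=[2.0, 4.0, 6.0, 8.0])


@pytest.fixture
def linear_iv_data(rng):
    """Weak-instrument sample with a strictly linear effect h(x) = x."""
    n = 20_000
    z = rng.binomial(1, 0.5, n) - 0.5
    u = rng.standard_normal(n)
    x = 0.15 * z + u + rng.standard_normal(n)
    y = x + u + rng.standard_normal(n)
    return IVDataset(z=z, x=x, y=y, u=u)
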