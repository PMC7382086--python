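import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rmtl import CompetingRisksSample

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_sample() -> CompetingRisksSample:
    """Four subjects: events of interest at 1 and 3, a competing event at 2,
    censoring at 4. All toy expectations in the tests are hand-computed from
    the product-limit recursion."""
    return CompetingRisksSample([1.0, 2.0, 3.0, 4.0], [1, 2, 1, 0])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)


def make_random_sample(
    rng: np.random.Generator,
    n: int = 60,
    p1: float = 0.7,
    censor_upper: float | None = None,
    group: str | None = None,
) -> CompetingRisksSample:
    """Simple exponential competing-risks draw used by property tests."""
    cause = np.where(rng.random(n) < p1, 1, 2)
    t = np.where(cause == 1, rng.exponential(8.0, n), rng.exponential(10.0, n))
    if censor_upper is not None:
        c = rng.uniform(0.0, censor_upper, n)
        cause = np.where(c < t, 0, cause)
        t = np.minimum(t, c)
    return CompetingRisksSample(t, cause, group=group)
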