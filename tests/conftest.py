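import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from crossurv.simulate import Exponential, apply_censoring, sample_survival_times
from crossurv.simulate import CensoringSpec
from crossurv.survcore import SurvivalSample


@pytest.fixture
def toy_pair():
    """Four subjects, all events, alternating groups: the hand example."""
    s1 = SurvivalSample([1.0, 3.0], [1, 1], group=1)
    s2 = SurvivalSample([2.0, 4.0], [1, 1], group=2)
    return s1, s2


@pytest.fixture
def mirrored_pair():
    """Two identical arms: every two-sample statistic should vanish."""
    times = [1.0, 2.0, 3.0, 4.0, 5.0]
    status = [1, 1, 0, 1, 1]
    return (SurvivalSample(times, status, group=1),
            SurvivalSample(times, status, group=2))


def exp_pair(n1=30, n2=30, rate=0.25, seed=0, censor_limit=None):
    """A null exponential replicate pair, optionally uniformly censored."""
    rng = np.random.default_rng(seed)
    law = Exponential(rate)
    spec = (CensoringSpec("none") if censor_limit is None
            else CensoringSpec("uniform", a=censor_limit, b=censor_limit))
    x1 = sample_survival_times(law, n1, rng)
    x2 = sample_survival_times(law, n2, rng)
    s1 = apply_censoring(x1, spec, rng, group=1)
    s2 = apply_censoring(x2, spec, rng, group=2)
    return s1, s2.relabel(2)


@pytest.fixture
def null_pair():
    return exp_pair(seed=42)
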