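import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

import pbifpet as p


@pytest.fixture(scope="session")
def healthy_template():
    return p.make_template_if(p.group_profile("healthy"))


@pytest.fixture(scope="session")
def small_healthy_cohort():
    """8 healthy subjects with measured plasma and TACs."""
    return p.sample_cohort(p.group_profile("healthy"), 8, seed=11)


@pytest.fixture(scope="session")
def small_healthy_fits(small_healthy_cohort):
    return p.fit_cohort_ifs(small_healthy_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
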