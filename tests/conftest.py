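import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hospexp import generate_fixture

settings.register_profile(
    "default", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def config():
    """A small synthetic configuration shared across tests (read-only)."""
    return generate_fixture(seed=7, population_size=2000, cycles_per_year=6)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def tuned_unmet_config(seed=7, population_size=3000, cycles_per_year=8):
    """Fixture where every doctor sits in the 50% over-prescription regime with
    zero public-welfare damping.

    Incomes are set far below the expected-income line at any admissible
    workload (expected income at 40 h is ~14.4 kCNY), the comparison direction
    is the economically standard one (unmet expectations drive
    over-prescription), and the responsibility index is zero at baseline
    subsidies because the index only starts rising above the baseline ratio.
    """
    cfg = generate_fixture(seed=seed, population_size=population_size,
                           cycles_per_year=cycles_per_year)
    cfg = cfg.model_copy(deep=True)
    cfg.overrx_rule.condition_swapped = True
    cfg.doctor_params.income_by_title = {
        t: 5000.0 for t in cfg.doctor_params.income_by_title
    }
    cfg.policy.responsibility_start = 1.0
    return cfg
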