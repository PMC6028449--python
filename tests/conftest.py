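import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cdepa.rules import default_ruleset
from cdepa.stats import ContingencyTable

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rules():
    return default_ruleset()


@pytest.fixture(scope="session")
def study_table():
    """The validation study's 2x2 counts (index test vs gold standard)."""
    return ContingencyTable(tp=63, fp=46, fn=2, tn=62)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


def all_no(rules):
    return {sid: False for sid in rules.ids}


@pytest.fixture(scope="session")
def calibrated_cohort_10k():
    """One large simulated cohort shared by the calibration checks."""
    from cdepa.simulate import default_config, simulate_cohort

    cfg = default_config(n=10_000, seed=20240915)
    return cfg, simulate_cohort(cfg)
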