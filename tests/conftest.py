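import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def opponents():
    from coopddm.task import build_opponents

    return build_opponents()


@pytest.fixture(scope="session")
def small_study():
    """One modest synthetic study shared by read-only tests."""
    from coopddm.cohort import generate_study

    return generate_study(n_subjects=6, seed=11)


@pytest.fixture(scope="session")
def small_valid(small_study):
    from coopddm.stats import clean_trials

    valid, _ = clean_trials(small_study.trials)
    return valid
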