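import dataclasses

import numpy as np
import pytest
from hypothesis import settings

import wisdomsim as ws

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


def scaled_config(factor: float, **overrides) -> ws.TrialConfig:
    """Default design scaled down to a smaller cohort (accrual pattern and
    all rates preserved)."""
    base = ws.default_wisdom_config()
    counts = tuple(int(round(c * factor)) for c in base.accrual_counts)
    return dataclasses.replace(
        base, n_total=sum(counts), accrual_counts=counts, **overrides
    )


def no_bias_config(factor: float = 0.1) -> ws.TrialConfig:
    """Both arms effectively annual: every stratum's personalized interval
    equals the annual interval, so any asymmetry between arms is spurious."""
    base = scaled_config(factor)
    strata = tuple(
        dataclasses.replace(s, personalized_interval_years=base.annual_arm_interval_years)
        for s in base.strata
    )
    return dataclasses.replace(base, strata=strata)


@pytest.fixture(scope="session")
def default_config() -> ws.TrialConfig:
    return ws.default_wisdom_config()


@pytest.fixture(scope="session")
def small_config() -> ws.TrialConfig:
    return scaled_config(0.01)  # 650 women


@pytest.fixture(scope="session")
def small_trial(small_config) -> ws.TrialData:
    return ws.run_single_trial(small_config, rng=123)


@pytest.fixture(scope="session")
def medium_trial() -> ws.TrialData:
    return ws.run_single_trial(scaled_config(0.2), rng=7)
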