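import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from herniacea import (
    LifeTable,
    ModelParameters,
    PainDistribution,
    base_case_life_table,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def base_params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def life_table() -> LifeTable:
    return base_case_life_table()


def flat_life_table(q: float = 0.1, ex: float = 10.0, lo: int = 40, hi: int = 80) -> LifeTable:
    """Constant-hazard life table for hand-checkable toy models."""
    ages = np.arange(lo, hi + 1)
    return LifeTable(age=ages, q=np.full(len(ages), q), ex=np.full(len(ages), ex))


@pytest.fixture
def toy_params() -> ModelParameters:
    """Small two-pain-level cohort amenable to exhaustive path enumeration."""
    return ModelParameters(
        starting_age=50,
        time_horizon=3,
        cohort_size=1.0,
        repair_rate=0.6,
        risk_recurrent=0.2,
        risk_contralateral=0.1,
        complication_risk=0.25,
        complication_mortality=0.2,  # premature-death risk 0.05
        discount_rate=0.0,
        half_cycle_correction=False,
        pain_untreated=PainDistribution(
            {"none": 0.5, "mild": 0.0, "moderate": 0.0, "severe": 0.5}
        ),
        pain_repaired=PainDistribution(
            {"none": 0.8, "mild": 0.2, "moderate": 0.0, "severe": 0.0}
        ),
        pain_recurrent=PainDistribution(
            {"none": 0.3, "mild": 0.0, "moderate": 0.0, "severe": 0.7}
        ),
    )


@pytest.fixture
def toy_life_table() -> LifeTable:
    return flat_life_table(q=0.1, ex=10.0, lo=45, hi=60)
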