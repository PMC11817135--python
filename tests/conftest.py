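import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from actimage.io import Condition
from actimage.synthetic import EASY_PROFILES, generate_subject

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cohort():
    """Two subjects per condition, three full days each (deterministic)."""
    cohort = {}
    for i, cond in enumerate(Condition):
        cohort[cond] = [
            generate_subject(
                EASY_PROFILES[cond],
                days=3,
                seed=100 * i + j,
                subject_id=f"{cond.value}_{j}",
                condition=cond,
            )
            for j in range(2)
        ]
    return cohort


@pytest.fixture
def rng():
    return np.random.default_rng(42)
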