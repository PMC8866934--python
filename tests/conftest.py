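import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ctcstrat as cs

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cohort() -> cs.Cohort:
    """A compact synthetic cohort shared by fast unit tests."""
    return cs.generate_cohort(
        cs.SimConfig(n_patients=20, cells_per_patient_mean=25,
                     bone_met_prevalence=0.5, seed=11)
    )


@pytest.fixture(scope="session")
def bm_matrix(small_cohort) -> cs.CohortMatrix:
    return cs.build_matrix(small_cohort, cls="eCTC", target="BM")


@pytest.fixture(scope="session")
def os_matrix(small_cohort) -> cs.CohortMatrix:
    return cs.build_matrix(small_cohort, cls="eCTC", target="OS")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
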