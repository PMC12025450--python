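import numpy as np
import pytest

from predinc import (
    BinaryDesign,
    SurvivalDesign,
    calibrate_weibull_scale,
    generate_binary_cohort,
    generate_survival_cohort,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def binary_cohort_small():
    """Balanced binary cohort, n = 400 — cheap input for fit/measure tests."""
    return generate_binary_cohort(BinaryDesign(event_rate=0.5, n=400), seed=7)


@pytest.fixture(scope="session")
def survival_scale_50():
    return calibrate_weibull_scale(SurvivalDesign(incidence_rate=0.5, n=1))


@pytest.fixture(scope="session")
def survival_cohort_small(survival_scale_50):
    """Type I-censored survival cohort, 50% incidence, n = 400."""
    d = SurvivalDesign(incidence_rate=0.5, n=400, scale=survival_scale_50)
    return generate_survival_cohort(d, seed=11)
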