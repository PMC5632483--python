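import numpy as np
import pytest

from coxspline import SimulationConfig, SurvivalData, simulate_cohort


@pytest.fixture(scope="session")
def cohort5000():
    """Default-configuration cohort at the full study size."""
    return simulate_cohort(SimulationConfig(n=5000, seed=42))


@pytest.fixture(scope="session")
def cohort1000():
    """Smaller seeded cohort for fit-level checks."""
    return simulate_cohort(SimulationConfig(n=1000, seed=7))


@pytest.fixture
def tiny_all_events():
    """Three subjects, distinct event times 1 < 2 < 3, all events."""
    return SurvivalData(time=[1.0, 2.0, 3.0], event=[1, 1, 1], exposure=[0.0, 0.0, 0.0])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
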