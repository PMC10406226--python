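import numpy as np
import pytest

from drinkdyn.model import InitialConditions, ModelParameters
from drinkdyn.references import MEDIAN_ICS, POPULATION_PARAMS
from drinkdyn.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def pop_params() -> ModelParameters:
    return POPULATION_PARAMS


@pytest.fixture(scope="session")
def median_ics() -> InitialConditions:
    return MEDIAN_ICS


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Three patients with zero observation noise and no missing days."""
    spec = CohortSpec(n_patients=3, sigma2=0.0, missingness=0.0, seed=42)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Six patients at the small-noise validation conditions."""
    spec = CohortSpec(n_patients=6, sigma2=0.25, missingness=0.1, seed=7)
    return generate_cohort(spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
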