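import numpy as np
import pytest

from heckmansel import SimParams, apply_mnar, calibrate_intercept, generate_complete
from heckmansel.montecarlo import model_data_from_cohort


@pytest.fixture(scope="session")
def default_params():
    return SimParams()


@pytest.fixture(scope="session")
def mnar_params():
    """Default study conditions with the selection intercept calibrated to 60% observed."""
    return calibrate_intercept(SimParams())


@pytest.fixture(scope="session")
def mnar_cohort(mnar_params):
    cohort = generate_complete(mnar_params, seed=101)
    return apply_mnar(cohort, mnar_params, seed=102)


@pytest.fixture(scope="session")
def mnar_data(mnar_cohort):
    return model_data_from_cohort(mnar_cohort.frame)


@pytest.fixture(scope="session")
def null_params():
    """Selection depends on treatment and distance only: rho = 0 by construction."""
    return calibrate_intercept(SimParams(sel_alpha_k=0.0))


@pytest.fixture(scope="session")
def null_data(null_params):
    cohort = generate_complete(null_params, seed=201)
    cohort = apply_mnar(cohort, null_params, seed=202)
    return model_data_from_cohort(cohort.frame)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
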