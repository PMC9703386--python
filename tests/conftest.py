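import numpy as np
import pytest

from natmet import reference_params
from natmet.simulate import ScreeningProgram, simulate_natural_history


@pytest.fixture(scope="session")
def ref_params():
    return reference_params()


@pytest.fixture(scope="session")
def product_params():
    return reference_params("product")


@pytest.fixture(scope="session")
def unscreened_cohort(ref_params):
    """Medium unscreened cohort shared across likelihood/inference tests."""
    return simulate_natural_history(ref_params, None, 1500, seed=101)


@pytest.fixture(scope="session")
def screened_cohort(ref_params):
    """Screened cohort (2-yearly program) shared across tests."""
    return simulate_natural_history(ref_params, ScreeningProgram(interval=2.0), 1500, seed=202)


@pytest.fixture()
def rng():
    return np.random.default_rng(991)
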