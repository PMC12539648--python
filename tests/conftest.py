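import pytest
from hypothesis import settings

from aortagnr.config import load_params
from aortagnr.gnr_equilibrium import GnRParams, init_homeostatic
from aortagnr.insult_model import InsultParams

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return load_params()


@pytest.fixture(scope="session")
def homeostatic(params):
    """(baseline in-vivo state, homeostatic targets)."""
    return init_homeostatic(params)


@pytest.fixture(scope="session")
def targets(homeostatic):
    return homeostatic[1]


@pytest.fixture(scope="session")
def baseline_state(homeostatic):
    return homeostatic[0]


@pytest.fixture(scope="session")
def gnr(params):
    return GnRParams.from_params(params)


@pytest.fixture(scope="session")
def table2_mean_insults():
    """Mean optimal insult triple over the reported optimization trials."""
    return InsultParams(theta_delta_max=0.0594, theta_gc_max=0.0080, g=6.21)
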