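import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from pigletbrain.model import InputTrace, simulate, steady_state, baseline_inputs
from pigletbrain.parameters import default_parameters, optimised_parameters
from pigletbrain.synth import make_protocol


@pytest.fixture(scope="session")
def p_default():
    return default_parameters()


@pytest.fixture(scope="session")
def p_optimised():
    return optimised_parameters()


@pytest.fixture(scope="session")
def baseline_state(p_default):
    return steady_state(p_default)


@pytest.fixture(scope="session")
def hi_protocol():
    """Default closed-loop HI protocol (shared; read-only)."""
    return make_protocol()


@pytest.fixture(scope="session")
def hi_run_default(p_default, hi_protocol):
    u, _ = hi_protocol
    return simulate(p_default, u)


@pytest.fixture(scope="session")
def hi_run_optimised(p_optimised, hi_protocol):
    u, _ = hi_protocol
    return simulate(p_optimised, u)


@pytest.fixture()
def constant_inputs(p_default):
    return InputTrace.constant(7200.0, sao2=0.96, pa=p_default.pa_n, n=121)
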