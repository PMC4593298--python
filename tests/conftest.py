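import numpy as np
import pytest
from scipy.optimize import fsolve

from apblock.cellmodels import get_model
from apblock.engine import PacingProtocol, pace_to_steady


@pytest.fixture(scope="session")
def demo_model():
    return get_model("sixcurrent_demo")


@pytest.fixture(scope="session")
def protocol(demo_model):
    return PacingProtocol.for_model(demo_model, frequency=1.0, max_paces=300)


@pytest.fixture(scope="session")
def control_steady(demo_model, protocol):
    """Drug-free 1 Hz steady state; shared by many tests (expensive)."""
    result = pace_to_steady(demo_model, demo_model.default_parameters, protocol)
    assert result.converged
    return result


@pytest.fixture(scope="session")
def equilibrium_state(demo_model, control_steady):
    """Resting equilibrium found by root-finding on the RHS (independent
    of the pacing engine)."""
    params = demo_model.default_parameters

    def rhs0(y):
        return demo_model.rhs(0.0, y, params, 0.0)

    eq = fsolve(rhs0, control_steady.end_state, xtol=1e-13)
    assert np.abs(rhs0(eq)).max() < 1e-10
    return eq
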