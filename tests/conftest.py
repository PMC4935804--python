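import numpy as np
import pytest

from nfkbpulse import ModelParameters, parse_protocol, simulate_cell, steady_state


@pytest.fixture(scope="session")
def nominal():
    return ModelParameters()


@pytest.fixture(scope="session")
def resting_state(nominal):
    return steady_state(nominal)


@pytest.fixture(scope="session")
def single_pulse_traj(nominal):
    """Nominal cell, one 5-min 10 ng/ml TNFα pulse, 420 min."""
    return simulate_cell(nominal, parse_protocol("T@0", t_end=420.0))


@pytest.fixture(scope="session")
def two_pulse_60_traj(nominal):
    return simulate_cell(nominal, parse_protocol("T@0,T@60", t_end=360.0))
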