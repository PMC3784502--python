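import numpy as np
import pytest

import dcx
from dcx.experiments import steady_state


@pytest.fixture(scope="session")
def params():
    return dcx.default_parameters()


@pytest.fixture(scope="session")
def normal_cell(params):
    return dcx.make_cell_model("normal", params=params)


@pytest.fixture(scope="session")
def sw480_cell(params):
    return dcx.make_cell_model("SW480", params=params)


@pytest.fixture(scope="session")
def base_network(normal_cell):
    net, y0 = dcx.assemble(normal_cell)
    return net, y0


@pytest.fixture(scope="session")
def base_steady_state(normal_cell):
    """Steady state of the calibrated normal-cell model (shared)."""
    net, ss = steady_state(normal_cell)
    return net, ss


def bcat_weights(net):
    return np.array([g.composition().get("BCAT", 0) for g in net.species], float)


def count_weights(net, type_name):
    return np.array([g.composition().get(type_name, 0) for g in net.species], float)
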