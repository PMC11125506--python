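import numpy as np
import pytest

from fsstdp.inputgen import make_squared_pulse, make_von_mises
from fsstdp.neuron import NeuronParams
from fsstdp.plasticity import PlasticityParams
from fsstdp.simulate import SimParams


@pytest.fixture
def pparams():
    return PlasticityParams()


@pytest.fixture
def nparams():
    return NeuronParams()


@pytest.fixture
def small_structure():
    """Small squared-pulse structure for fast network runs."""
    return make_squared_pulse(400, 80, 24.0)


@pytest.fixture
def small_sim():
    return SimParams(n_inh=80, w_init=0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
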