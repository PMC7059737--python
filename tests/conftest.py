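import numpy as np
import pytest

from spikebp.lif import NeuronParams
from spikebp.models import FC, ArchitectureSpec, InitConfig, Output, build


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def lif_params():
    return NeuronParams(v_th=1.0, tau_m=100.0)


def make_fc_network(n_in, hidden, n_out, seed=0, dropout_p=0.0):
    """Small fully connected spiking network for oracle/training tests."""
    layers = tuple(FC(h) for h in hidden) + (Output(n_out),)
    arch = ArchitectureSpec("test-fc", layers)
    # input treated as a flat (1, 1, n_in) image so build() can size the stack
    return build(arch, (1, 1, n_in), init=InitConfig(kappa=2.0, seed=seed),
                 dropout_p=dropout_p)


@pytest.fixture
def fc_network_factory():
    return make_fc_network
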