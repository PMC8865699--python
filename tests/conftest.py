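import numpy as np
import pytest

from engramnet.network import LIFParams
from engramnet.plasticity import PlasticityParams
from engramnet.protocols import grow_network, repeated_stimulation


#: fast-plasticity parameters of the down-scaled reference network
SCALED_PLAST = dict(tau_ca_s=1.0, beta_a=0.4, beta_d=0.4, delta_t_s_ms=10.0)


@pytest.fixture(scope="session")
def lif():
    return LIFParams()


@pytest.fixture(scope="session")
def grown_scaled():
    """A 1000E/250I network grown to its homeostatic equilibrium.

    Shared across tests; always work on ``.net.clone()`` to keep the
    grown state pristine.
    """
    g = grow_network(N_E=1000, N_I=250, t_growth_s=100.0,
                     plast=PlasticityParams(**SCALED_PLAST),
                     seed=11, n_extra=1)
    return g


@pytest.fixture(scope="session")
def engram_scaled(grown_scaled):
    """Engram encoded by repeated stimulation on a clone of the grown
    network; plasticity frozen afterwards.  Returns (net, engram indices,
    stimulation result)."""
    net = grown_scaled.net.clone()
    rng = np.random.default_rng(21)
    engram = np.sort(rng.choice(net.conn.N_E, size=100, replace=False))
    res = repeated_stimulation(net, engram, n_cycles=4, stim_s=15.0,
                               relax_s=15.0, amp=1.1, record_every_s=5.0,
                               freeze_after=True)
    return net, engram, res
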