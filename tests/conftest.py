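import numpy as np
import pytest

from synenergy.core import PlasticityParams
from synenergy.neuron import build_neuron, run_sim
from synenergy.protocols import ProtocolSpec


@pytest.fixture(scope="session")
def params():
    return PlasticityParams()


@pytest.fixture(scope="session")
def neuron():
    return build_neuron()


def _protocol(pre_events=None, pulses=None, duration=0.2):
    return ProtocolSpec(
        pre_times=np.empty(0),
        somatic_pulses=pulses or [],
        duration=duration,
        pre_events=pre_events or {},
    )


@pytest.fixture(scope="session")
def quiet_trace(neuron):
    """500 ms of zero-input activity, all compartments."""
    return run_sim(neuron, _protocol(duration=0.5), 0.5, 1e-4)


@pytest.fixture(scope="session")
def bap_trace(neuron):
    """Single somatic pulse (1 nA, 3 ms) driving one backpropagating spike."""
    return run_sim(neuron, _protocol(pulses=[(0.05, 1.0, 3.0)]), 0.2, 1e-4)


def count_spikes(v, threshold=0.0):
    """Local maxima above threshold in a voltage trace."""
    v = np.asarray(v)
    return int(((v[1:-1] > v[:-2]) & (v[1:-1] >= v[2:]) & (v[1:-1] > threshold)).sum())
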