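import numpy as np
import pytest

from thermoclamp.neuron import NeuronParams
from thermoclamp.traces import Sweep


@pytest.fixture(scope="session")
def passive_cell() -> NeuronParams:
    """100 MΩ / 100 pF purely passive cell (tau = 10 ms)."""
    return NeuronParams.passive(100.0, 100.0)


@pytest.fixture(scope="session")
def leak_kv_cell() -> NeuronParams:
    """Leak + delayed-rectifier cell for leak-subtraction oracles."""
    return NeuronParams(
        c_pf=100.0, g_leak_ns=2.0, e_leak_mv=-75.0,
        g_kir_ns=0.0, g_na_ns=0.0, g_kv_ns=360.0,
    )


def make_sweep(values, rate_hz=2.0e4, channel="voltage", **kwargs) -> Sweep:
    return Sweep.from_values(np.asarray(values, dtype=float), rate_hz, channel, **kwargs)
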