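import numpy as np
import pytest

import kinetrace as kt


@pytest.fixture
def line_trace():
    """Exact straight line y = 2t + 1 on t = 0..10."""
    t = np.linspace(0.0, 10.0, 21)
    return kt.KineticTrace("line 1", 1.0, t, 2.0 * t + 1.0)


@pytest.fixture
def mm_trace():
    """Noiseless progress curve, S0 = 10, KM = 50, Vmax = 1 (true v0 = 1/6)."""
    t = np.arange(0.0, 100.5, 0.5)
    s = kt.schnell_mendoza_curve(t, 10.0, 50.0, 1.0)
    return kt.KineticTrace("10", 10.0, t, s)


@pytest.fixture
def noiseless_sm_dataset():
    """Four noiseless substrate-depletion traces, KM = 100, Vmax = 5."""
    t = np.arange(0.0, 60.5, 0.5)
    traces = [
        kt.KineticTrace(f"{s0:g}", s0, t, kt.schnell_mendoza_curve(t, s0, 100.0, 5.0))
        for s0 in (20.0, 50.0, 100.0, 200.0)
    ]
    return kt.KineticDataset(traces)
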