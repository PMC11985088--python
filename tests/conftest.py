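import numpy as np
import pytest

from singlechan.gatingsim import (
    AcquisitionConfig,
    VoltageProtocol,
    slow_gate_model,
    wildtype_model,
)
from singlechan.trace import Trace


@pytest.fixture
def wt_model():
    return wildtype_model()


@pytest.fixture
def square_trace():
    """Noiseless square wave 0 <-> 10 pA, 100 ms dwells, fs 5 kHz, 2 s."""
    fs = 5000.0
    dwell = int(0.1 * fs)
    cycle = np.concatenate([np.zeros(dwell), np.full(dwell, 10.0)])
    samples = np.tile(cycle, 10)
    return Trace(samples, fs=fs, voltage=100.0, genotype="sq")


@pytest.fixture
def flat_slow_model():
    """Factory: voltage-independent slow gate at a given open fraction."""

    def make(p_open, g_true=174.0, k_close0=200.0):
        return slow_gate_model("flat", g_true, p_neg=p_open, p_pos=p_open,
                               k_close0=k_close0)

    return make


@pytest.fixture
def fast_acq():
    """Cheap acquisition for flicker-free simulations (low oversampling)."""

    def make(noise_sd, duration, oversample=2):
        return AcquisitionConfig(
            noise_sd=noise_sd, duration=duration, oversample_factor=oversample
        )

    return make


@pytest.fixture
def single_voltage_protocol():
    def make(voltage, duration):
        return VoltageProtocol(voltages=(float(voltage),), per_voltage_duration=duration)

    return make
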