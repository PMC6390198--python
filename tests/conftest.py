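import numpy as np
import pytest

from entophys.recording import Sweep


def make_sweep(voltage, sample_rate=20000.0, stim_onset=0.1,
               stim_offset=None, step_amplitude=0.0, sweep_kind="step",
               current=None):
    """Sweep from a raw voltage array with sensible defaults."""
    voltage = np.asarray(voltage, dtype=float)
    n = len(voltage)
    t = np.arange(n) / sample_rate
    if stim_offset is None:
        stim_offset = t[-1]
    if current is None:
        current = np.where((t >= stim_onset) & (t < stim_offset),
                           step_amplitude, 0.0)
    return Sweep(time=t, voltage=voltage, current=current,
                 sample_rate=sample_rate, stim_onset=stim_onset,
                 stim_offset=stim_offset, step_amplitude=step_amplitude,
                 sweep_kind=sweep_kind)


@pytest.fixture(scope="session")
def fan_recording():
    """One simulated fan cell, shared across tests (generation is slow)."""
    from entophys.synth import fan_cell, generate_model_cell

    return generate_model_cell(fan_cell(), seed=1234, cell_id="fan-fixture")


@pytest.fixture(scope="session")
def stellate_recording():
    from entophys.synth import generate_model_cell, stellate_cell

    return generate_model_cell(stellate_cell(), seed=4321,
                               cell_id="stellate-fixture")
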