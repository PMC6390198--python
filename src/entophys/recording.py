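"""In-memory containers for current-clamp recordings.

A :class:`Sweep` is one time-aligned (time, command current, voltage)
record; a :class:`CellRecording` bundles all sweeps of one cell with its
animal- and cell-level metadata and is the unit of QC and feature
extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .exceptions import NonUniformSamplingError

SWEEP_KINDS = ("step", "rheobase_step", "zap", "spontaneous")
GENOTYPES = ("+/+", "-/-", "wt")
REGIONS = ("MEC", "LEC")


@dataclass
class Sweep:
    """One protocol sweep.

    time is in seconds from sweep start, voltage in mV, current (the command
    waveform) in pA.  ``stim_onset``/``stim_offset`` delimit the stimulus in
    seconds; ``step_amplitude`` is the commanded step in pA (0 for ZAP and
    spontaneous sweeps).
    """

    time: np.ndarray
    voltage: np.ndarray
    current: np.ndarray
    sample_rate: float
    stim_onset: float
    stim_offset: float
    step_amplitude: float = 0.0
    sweep_kind: str = "step"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if not (len(self.time) == len(self.voltage) == len(self.current)):
            raise ValueError("time, voltage and current must share a length")
        if self.sweep_kind not in SWEEP_KINDS:
            raise ValueError(f"unknown sweep_kind {self.sweep_kind!r}")
        if not np.all(np.isfinite(self.voltage)):
            raise ValueError("voltage contains non-finite samples")
        if self.stim_onset >= self.stim_offset:
            raise ValueError("stim_onset must precede stim_offset")
        if self.stim_offset > self.time[-1] + self.dt:
            raise ValueError("stim_offset lies beyond the sweep")
        self.validate_uniform()

    @property
    def dt(self) -> float:
        """Sample period in seconds."""
        return 1.0 / self.sample_rate

    def validate_uniform(self) -> None:
        d = np.diff(self.time)
        if len(d) == 0 or np.any(d <= 0):
            raise NonUniformSamplingError("time must be strictly increasing")
        if np.max(np.abs(d - self.dt)) > self.dt:
            raise NonUniformSamplingError(
                "sampling deviates from 1/sample_rate by more than one period"
            )

    def index_at(self, t: float) -> int:
        """Index of the sample closest to time ``t`` (seconds)."""
        return int(round((t - self.time[0]) * self.sample_rate))

    def slice_time(self, t0: float, t1: float) -> slice:
        """Half-open sample slice covering [t0, t1)."""
        i0 = max(0, self.index_at(t0))
        i1 = min(len(self.time), self.index_at(t1))
        return slice(i0, max(i0, i1))


@dataclass
class CellRecording:
    """All sweeps plus metadata for one recorded cell."""

    cell_id: str
    animal_id: str
    genotype: str
    sweeps: list[Sweep] = field(default_factory=list)
    age_group: str = ""
    sex: str = ""
    region: str = "MEC"
    setup: str = ""
    bridge_balance: float = float("nan")  # MOhm
    ground_truth: Optional[dict] = None   # simulator parameters, if synthetic

    def of_kind(self, kind: str) -> list[Sweep]:
        return [s for s in self.sweeps if s.sweep_kind == kind]

    def steps(self) -> list[Sweep]:
        return sorted(self.of_kind("step"), key=lambda s: s.step_amplitude)

    def rheobase_steps(self) -> list[Sweep]:
        return sorted(
            self.of_kind("rheobase_step"), key=lambda s: s.step_amplitude
        )

    def step_at(self, amplitude: float, tol: float = 0.5) -> Sweep:
        for s in self.of_kind("step"):
            if abs(s.step_amplitude - amplitude) <= tol:
                return s
        raise KeyError(f"no step sweep at {amplitude} pA")
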