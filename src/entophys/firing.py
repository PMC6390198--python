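"""Rheobase and frequency-current (F-I) analysis.

Rheobase is the amplitude of the first sweep in the 10-pA ramp family that
elicits at least one AP.  F-I points carry the average firing rate (spike
count over the 1-s step), the instantaneous rate of the first and last
spike pairs (f0, f_ss) and the post-step AHP relative to the pre-stimulus
baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .config import AnalysisConfig, DEFAULT_CONFIG
from .recording import Sweep
from .spikes import detect_action_potentials


@dataclass
class RheobaseResult:
    rheobase: Optional[float]   # pA; None when no sweep spiked
    max_tested: float           # pA
    sweep_index: Optional[int]

    @property
    def reached(self) -> bool:
        return self.rheobase is not None


def rheobase(
    sweeps: Sequence[Sweep], config: AnalysisConfig = DEFAULT_CONFIG
) -> RheobaseResult:
    """First spiking amplitude of an increasing rheobase-step family."""
    ordered = sorted(sweeps, key=lambda s: s.step_amplitude)
    if not ordered:
        raise ValueError("no sweeps supplied")
    amps = [s.step_amplitude for s in ordered]
    if np.any(np.diff(amps) <= 0):
        raise ValueError("rheobase sweeps must have distinct amplitudes")
    for i, s in enumerate(ordered):
        if len(detect_action_potentials(s, config)) > 0:
            return RheobaseResult(rheobase=float(s.step_amplitude),
                                  max_tested=float(amps[-1]), sweep_index=i)
    return RheobaseResult(rheobase=None, max_tested=float(amps[-1]),
                          sweep_index=None)


@dataclass
class FICurvePoint:
    current: float              # pA
    f_avg: float                # Hz, count / step duration
    f0: Optional[float]         # Hz, 1000 / first ISI(ms)
    f_ss: Optional[float]       # Hz, 1000 / last ISI(ms)
    post_step_ahp: Optional[float]  # mV, post-offset min minus baseline
    n_spikes: int


def fi_curve(
    sweeps: Sequence[Sweep],
    config: AnalysisConfig = DEFAULT_CONFIG,
    freq_range: tuple[float, float] = (200.0, 500.0),
    ahp_range: tuple[float, float] = (50.0, 500.0),
) -> list[FICurvePoint]:
    """F-I points from positive step sweeps.

    Rates are reported for steps within ``freq_range`` (pA) and the
    post-step AHP for steps within ``ahp_range``; points with fewer than
    two spikes carry absent f0/f_ss.
    """
    win = config.windows
    points: list[FICurvePoint] = []
    for s in sorted(sweeps, key=lambda x: x.step_amplitude):
        amp = s.step_amplitude
        in_freq = freq_range[0] <= amp <= freq_range[1]
        in_ahp = ahp_range[0] <= amp <= ahp_range[1]
        if not (in_freq or in_ahp):
            continue
        peaks = detect_action_potentials(s, config)
        duration = s.stim_offset - s.stim_onset
        f_avg = len(peaks) / duration if in_freq else np.nan
        f0 = f_ss = None
        if in_freq and len(peaks) >= 2:
            isis = np.diff(s.time[peaks])
            f0 = float(1.0 / isis[0])
            f_ss = float(1.0 / isis[-1])

        ahp = None
        if in_ahp:
            off = s.index_at(s.stim_offset)
            post_end = min(len(s.voltage),
                           off + int(round(win.post_stim_ms / 1000.0
                                           * s.sample_rate)))
            base_sl = s.slice_time(s.stim_onset - win.baseline_ms / 1000.0,
                                   s.stim_onset)
            if post_end > off:
                ahp = float(np.min(s.voltage[off:post_end])
                            - np.mean(s.voltage[base_sl]))
        points.append(FICurvePoint(
            current=float(amp),
            f_avg=float(f_avg) if in_freq else np.nan,
            f0=f0,
            f_ss=f_ss,
            post_step_ahp=ahp,
            n_spikes=len(peaks),
        ))
    return points
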