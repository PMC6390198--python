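"""Subthreshold resonance from ZAP (chirp) sweeps.

The impedance magnitude profile |Z(f)| is the spectral ratio of the
voltage response to the injected chirp current, smoothed with a moving
average in frequency.  The resonance frequency is the argmax of the
smoothed profile over the analysis band; when the argmax sits at the lower
band edge the cell is classified as non-resonant (a monotone low-pass
profile has no interior peak).  Traces containing APs are rejected, since
spikes invalidate the linear impedance estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import AnalysisConfig, DEFAULT_CONFIG
from .exceptions import NotEstimableError
from .recording import Sweep
from .spikes import detect_action_potentials


@dataclass
class ResonanceResult:
    resonance_frequency: float       # Hz
    is_resonant: bool
    frequencies: np.ndarray          # Hz, analysis band
    impedance: np.ndarray            # MOhm, smoothed |Z|
    q: float = 1.0                   # Z(f_res) / Z(low edge)
    method: str = "spectral_ratio"


def impedance_profile(zap: Sweep) -> tuple[np.ndarray, np.ndarray]:
    """Raw impedance magnitude |Z(f)| = |V(f)| / |I(f)| in MOhm.

    Uses the full-length FFT of the mean-subtracted voltage and current;
    1 mV/pA = 1000 MOhm.
    """
    v = zap.voltage - np.mean(zap.voltage)
    i = zap.current - np.mean(zap.current)
    n = len(v)
    freqs = np.fft.rfftfreq(n, d=zap.dt)
    vf = np.fft.rfft(v)
    if_ = np.fft.rfft(i)
    mag_i = np.abs(if_)
    floor = max(np.max(mag_i) * 1e-6, 1e-30)
    z = np.abs(vf) / np.maximum(mag_i, floor) * 1000.0  # MOhm
    return freqs, z


def resonance_frequency(
    zap: Sweep, config: AnalysisConfig = DEFAULT_CONFIG
) -> ResonanceResult:
    """Resonance frequency from a ZAP sweep.

    Raises :class:`NotEstimableError` when the trace contains APs.
    """
    if zap.sweep_kind != "zap":
        raise ValueError("resonance needs a zap sweep")
    if len(detect_action_potentials(zap, config)) > 0:
        raise NotEstimableError("ZAP trace contains action potentials")

    freqs, z = impedance_profile(zap)
    lo, hi = config.resonance.band_hz
    band = (freqs >= lo) & (freqs <= hi)
    if band.sum() < 5:
        raise NotEstimableError("analysis band unresolved at this length")
    f_band, z_band = freqs[band], z[band]

    df = f_band[1] - f_band[0]
    w = max(1, int(round(config.resonance.smooth_hz / df)))
    if w % 2 == 0:
        w += 1
    kernel = np.ones(w) / w
    pad = w // 2
    z_pad = np.r_[z_band[pad:0:-1], z_band, z_band[-2:-pad - 2:-1]]
    z_smooth = np.convolve(z_pad, kernel, mode="valid")

    arg = int(np.argmax(z_smooth))
    f_res = float(f_band[arg])
    # resonant = an interior peak that actually rises above the low-
    # frequency impedance (resonance strength Q), not spectral ripple on
    # a monotone low-pass profile
    q = float(z_smooth[arg] / z_smooth[0]) if z_smooth[0] > 0 else np.inf
    is_resonant = ((f_res - lo) > config.resonance.edge_tol_hz
                   and q >= config.resonance.min_q)
    return ResonanceResult(
        resonance_frequency=f_res,
        is_resonant=is_resonant,
        frequencies=f_band,
        impedance=z_smooth,
        q=q,
    )
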