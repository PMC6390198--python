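"""Action-potential detection and waveform features.

Detection uses a dV/dt onset criterion with a minimum-peak check and a
refractory merge window.  Waveform features follow the standard
current-clamp definitions: threshold at the maximum of the second
derivative of the voltage (computed analytically from a local cubic
polynomial fit, restricted to a short pre-peak window), amplitude from
threshold to peak, half-width at 50 % of the amplitude by linear
interpolation between samples, fAHP as the post-peak minimum, and DAP as
the post-fAHP maximum relative to the fAHP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import savgol_filter

from .config import AnalysisConfig, DEFAULT_CONFIG
from .recording import Sweep

log = logging.getLogger(__name__)


def detect_action_potentials(
    sweep: Sweep, config: AnalysisConfig = DEFAULT_CONFIG
) -> np.ndarray:
    """Indices of AP peaks in ``sweep.voltage``, strictly increasing.

    An AP starts where dV/dt crosses the onset criterion from below; its
    peak is the voltage maximum within the subsequent search window.  Peaks
    below the minimum-peak criterion are discarded, and peaks within the
    refractory window of an accepted peak are merged into it (a warning is
    logged when that happens).
    """
    sweep.validate_uniform()
    v = sweep.voltage
    dt_ms = 1000.0 * sweep.dt
    dvdt = np.diff(v) / dt_ms
    cfg = config.spike

    above = dvdt >= cfg.dvdt_threshold
    onsets = np.flatnonzero(above & ~np.r_[False, above[:-1]])
    if len(onsets) == 0:
        return np.empty(0, dtype=int)

    search = max(1, int(round(cfg.peak_search_ms / dt_ms)))
    refractory = cfg.refractory_ms / 1000.0

    peaks: list[int] = []
    for onset in onsets:
        stop = min(len(v), onset + 1 + search)
        peak = onset + int(np.argmax(v[onset:stop]))
        if v[peak] < cfg.min_peak:
            continue
        # must be a local maximum (not a ramp running off the window edge)
        if 0 < peak < len(v) - 1 and not (
            v[peak] >= v[peak - 1] and v[peak] >= v[peak + 1]
        ):
            continue
        if peaks and (sweep.time[peak] - sweep.time[peaks[-1]]) < refractory:
            log.warning(
                "spike at %.4f s within refractory window of previous; merged",
                sweep.time[peak],
            )
            continue
        if peaks and peak == peaks[-1]:
            continue
        peaks.append(peak)
    return np.asarray(peaks, dtype=int)


@dataclass
class APFeatures:
    """Waveform features of a single AP (voltages in mV, times in s)."""

    threshold: float
    amplitude: float
    half_width: float          # ms
    peak_time: float
    threshold_time: float
    fahp: Optional[float] = None
    dap: Optional[float] = None
    flags: tuple[str, ...] = ()


def _interp_crossing(t: np.ndarray, v: np.ndarray, level: float,
                     rising: bool) -> Optional[float]:
    """First time v crosses ``level`` in the stated direction, interpolated."""
    if rising:
        hit = (v[:-1] < level) & (v[1:] >= level)
    else:
        hit = (v[:-1] >= level) & (v[1:] < level)
    idx = np.flatnonzero(hit)
    if len(idx) == 0:
        return None
    i = idx[0]
    frac = (level - v[i]) / (v[i + 1] - v[i])
    return float(t[i] + frac * (t[i + 1] - t[i]))


def _smooth_window(n_samples: int, dt_ms: float, smooth_ms: float) -> int:
    w = int(round(smooth_ms / dt_ms))
    w = max(w, 5)
    if w % 2 == 0:
        w += 1
    return min(w, n_samples - (1 - n_samples % 2))


def ap_waveform_features(
    sweep: Sweep,
    ap_index: int,
    region: str = "MEC",
    config: AnalysisConfig = DEFAULT_CONFIG,
    peaks: Optional[np.ndarray] = None,
) -> APFeatures:
    """Waveform features of the AP whose ordinal number is ``ap_index``.

    fAHP and DAP are only measured for MEC cells; the DAP is reported
    absent when a following spike (doublet) falls inside the DAP window.
    """
    if peaks is None:
        peaks = detect_action_potentials(sweep, config)
    if not 0 <= ap_index < len(peaks):
        raise IndexError(f"ap_index {ap_index} out of range ({len(peaks)} APs)")

    peak = int(peaks[ap_index])
    t = sweep.time
    v = sweep.voltage
    dt_ms = 1000.0 * sweep.dt
    win = config.windows

    # --- threshold: max of the second derivative of a local cubic fit ---
    pre = max(0, peak - int(round(win.threshold_search_ms / dt_ms)))
    if ap_index > 0:
        pre = max(pre, int(peaks[ap_index - 1]) + 1)
    seg = slice(pre, peak + 1)
    if peak - pre < 4:
        raise ValueError("threshold search window is empty or too short")
    sw = _smooth_window(peak + 1 - pre, dt_ms, win.smooth_ms)
    v_s = savgol_filter(v[seg], sw, 3)
    d2 = savgol_filter(v[seg], sw, 3, deriv=2, delta=dt_ms)
    thr_i = int(np.argmax(d2[:-1]))  # exclude the peak sample itself
    threshold = float(v_s[thr_i])
    threshold_time = float(t[pre + thr_i])

    amplitude = float(v[peak] - threshold)
    flags: list[str] = []
    if amplitude <= 0:
        flags.append("non_positive_amplitude")

    # --- half-width at 50 % amplitude, interpolated crossings ---
    half_level = threshold + 0.5 * amplitude
    up = _interp_crossing(t[pre:peak + 1], v[pre:peak + 1], half_level, True)
    post_end = min(len(v), peak + 1 + int(round(5.0 / dt_ms)))
    down = _interp_crossing(t[peak:post_end], v[peak:post_end],
                            half_level, False)
    if up is None or down is None:
        half_width = float("nan")
        flags.append("half_width_unresolved")
    else:
        half_width = 1000.0 * (down - up)

    fahp = dap = None
    if region == "MEC":
        fahp_end = min(len(v), peak + 1 + int(round(win.fahp_ms / dt_ms)))
        fahp_i = peak + 1 + int(np.argmin(v[peak + 1:fahp_end]))
        fahp = float(v[fahp_i])
        if fahp > threshold:
            flags.append("fahp_above_threshold")
        dap_end = min(len(v), fahp_i + 1 + int(round(win.dap_ms / dt_ms)))
        next_peak = peaks[ap_index + 1] if ap_index + 1 < len(peaks) else None
        if next_peak is not None and next_peak < dap_end:
            dap = None  # doublet obscures the DAP
            flags.append("dap_obscured_by_doublet")
        elif dap_end > fahp_i + 1:
            dap = float(np.max(v[fahp_i + 1:dap_end]) - fahp)

    return APFeatures(
        threshold=threshold,
        amplitude=amplitude,
        half_width=half_width,
        peak_time=float(t[peak]),
        threshold_time=threshold_time,
        fahp=fahp,
        dap=dap,
        flags=tuple(flags),
    )


@dataclass
class TrainFeatures:
    """Per-AP and train statistics from a positive current step."""

    per_ap_amplitude: np.ndarray       # mV, by AP number
    per_ap_width_at_0mv: np.ndarray    # ms, NaN when the spike stays < 0 mV
    isi: np.ndarray                    # ms, by interval number
    isi1_over_isi2: Optional[float]
    adaptation_ratio: Optional[float]  # first ISI / last ISI
    n_spikes: int
    reason: Optional[str] = None


def spike_train_features(
    sweep: Sweep, config: AnalysisConfig = DEFAULT_CONFIG
) -> TrainFeatures:
    """AP amplitude, width at 0 mV and ISI as a function of AP number.

    The amplitude here is measured from threshold to peak per spike; the
    width at 0 mV uses interpolated up/down crossings of 0 mV and is absent
    (NaN) for spikes that never reach 0 mV.  ``isi1_over_isi2`` needs at
    least 3 spikes, the adaptation ratio (first/last ISI) at least 3.
    """
    peaks = detect_action_potentials(sweep, config)
    n = len(peaks)
    if n < 2:
        return TrainFeatures(
            per_ap_amplitude=np.empty(0),
            per_ap_width_at_0mv=np.empty(0),
            isi=np.empty(0),
            isi1_over_isi2=None,
            adaptation_ratio=None,
            n_spikes=n,
            reason="fewer than 2 APs",
        )

    t, v = sweep.time, sweep.voltage
    amp = np.empty(n)
    width0 = np.full(n, np.nan)
    for k, p in enumerate(peaks):
        feats = ap_waveform_features(sweep, k, region="LEC",
                                     config=config, peaks=peaks)
        amp[k] = feats.amplitude
        if v[p] > 0.0:
            lo = peaks[k - 1] if k > 0 else 0
            hi = peaks[k + 1] if k + 1 < n else len(v)
            up = _interp_crossing(t[lo:p + 1], v[lo:p + 1], 0.0, True)
            down = _interp_crossing(t[p:hi], v[p:hi], 0.0, False)
            if up is not None and down is not None:
                width0[k] = 1000.0 * (down - up)

    isi = 1000.0 * np.diff(t[peaks])
    isi1_over_isi2 = float(isi[0] / isi[1]) if n >= 3 else None
    adaptation = float(isi[0] / isi[-1]) if n >= 3 else None
    return TrainFeatures(
        per_ap_amplitude=amp,
        per_ap_width_at_0mv=width0,
        isi=isi,
        isi1_over_isi2=isi1_over_isi2,
        adaptation_ratio=adaptation,
        n_spikes=n,
    )
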