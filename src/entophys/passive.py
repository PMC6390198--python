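"""Passive membrane properties from subthreshold current steps.

Input resistance comes from the quadratic current-voltage relation
dV = R_N0*dI + c_AR*dI^2 fitted without intercept over the subthreshold
steps; R_N0 is the voltage-independent input resistance and c_AR the
coefficient of anomalous rectification.  The membrane time constant is the
larger time constant of a double-exponential fit to the onset of the
-300 pA response.  Sag ratio and rebound follow the standard definitions
for H-current-expressing neurons.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .config import AnalysisConfig, DEFAULT_CONFIG
from .exceptions import InsufficientDataError, UndefinedSagError
from .recording import Sweep
from .spikes import detect_action_potentials

log = logging.getLogger(__name__)


@dataclass
class InputResistanceFit:
    r_n0: float        # MOhm
    c_ar: float        # mV/pA^2
    residual_norm: float
    n_points: int


def fit_input_resistance(
    steps: Sequence[tuple[float, float]]
) -> InputResistanceFit:
    """Least-squares fit of dV = R*dI + c*dI^2 (no intercept).

    ``steps`` is a sequence of (dI in pA, steady-state dV in mV) pairs from
    sweeps that elicited no APs.  Returns R_N0 in MOhm (1 mV/pA = 1000 MOhm)
    and c_AR in mV/pA^2.  Requires at least 3 distinct current values.
    """
    pts = np.asarray(list(steps), dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
        raise InsufficientDataError("need >= 3 (dI, dV) points")
    di, dv = pts[:, 0], pts[:, 1]
    if len(np.unique(di)) < 3:
        raise InsufficientDataError("need >= 3 distinct current values")
    design = np.column_stack([di, di**2])
    if np.linalg.matrix_rank(design) < 2:
        raise InsufficientDataError("rank-deficient design")
    coef, *_ = np.linalg.lstsq(design, dv, rcond=None)
    resid = dv - design @ coef
    return InputResistanceFit(
        r_n0=float(coef[0] * 1000.0),
        c_ar=float(coef[1]),
        residual_norm=float(np.linalg.norm(resid)),
        n_points=len(di),
    )


@dataclass
class TauFit:
    tau: float                  # ms; the larger component
    taus: tuple[float, float]
    amplitudes: tuple[float, float]
    offset: float
    residual_norm: float
    single_exponential_fallback: bool = False


_TAU_BOUNDS = (0.1, 200.0)
#: smallest |amplitude| / step deflection for a fitted exponential
#: component to count as real when applying the larger-tau rule
_MIN_COMPONENT_FRACTION = 0.05


def average_sweeps(sweeps: Sequence[Sweep]) -> Sweep:
    """Pointwise voltage average of repeated, identically timed sweeps.

    Used for repeated hyperpolarizing steps before the tau / sag fits;
    sweeps must agree in length, sample rate and stimulus timing.
    """
    sweeps = list(sweeps)
    if not sweeps:
        raise ValueError("no sweeps to average")
    ref = sweeps[0]
    if len(sweeps) == 1:
        return ref
    for s in sweeps[1:]:
        if (len(s.voltage) != len(ref.voltage)
                or s.sample_rate != ref.sample_rate
                or s.stim_onset != ref.stim_onset
                or s.stim_offset != ref.stim_offset
                or s.step_amplitude != ref.step_amplitude):
            raise ValueError("sweeps differ in geometry or stimulus timing")
    v = np.mean([s.voltage for s in sweeps], axis=0)
    return Sweep(
        time=ref.time.copy(), voltage=v, current=ref.current.copy(),
        sample_rate=ref.sample_rate, stim_onset=ref.stim_onset,
        stim_offset=ref.stim_offset, step_amplitude=ref.step_amplitude,
        sweep_kind=ref.sweep_kind,
    )


def _varpro_design(t: np.ndarray, taus: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(t)]
                           + [np.exp(-t / tau) for tau in taus])


#: scale-free ridge on the exponential amplitudes: large enough to rule
#: out the near-cancelling amplitude pairs that arise when two time
#: constants approach each other, small enough not to bias a
#: well-separated fit measurably
_AMPLITUDE_RIDGE = 1e-3


def _ridge_amplitudes(design: np.ndarray, v: np.ndarray) -> np.ndarray:
    gram = design.T @ design
    penalty = _AMPLITUDE_RIDGE * np.diag(np.diag(gram))
    penalty[0, 0] = 0.0  # the offset is never penalized
    return np.linalg.solve(gram + penalty, design.T @ v)


def _fit_exponentials(
    t: np.ndarray, v: np.ndarray, n_components: int
) -> tuple[np.ndarray, np.ndarray, float]:
    """Variable-projection exponential fit.

    The amplitudes (and offset) are linear given the time constants, so
    they are profiled out exactly and only the taus are optimized, from a
    multistart grid over the bounded tau range.  Returns (taus,
    [offset, amplitudes...], residual norm).
    """
    lo, hi = _TAU_BOUNDS
    span = max(t[-1], 1.0)

    def residual(log_taus: np.ndarray) -> np.ndarray:
        taus = np.exp(log_taus)
        design = _varpro_design(t, taus)
        coef = _ridge_amplitudes(design, v)
        return design @ coef - v

    grid = np.geomspace(max(lo, span / 200.0), min(hi, 2.0 * span), 6)
    if n_components == 1:
        starts = [[g] for g in grid]
    else:
        starts = [[g1, g2] for i, g1 in enumerate(grid)
                  for g2 in grid[i + 1:]]
    candidates = []
    for start in starts:
        sol = least_squares(
            residual, np.log(start),
            bounds=(np.log(lo), np.log(hi)), xtol=1e-12, ftol=1e-12,
            max_nfev=200,
        )
        taus = np.exp(sol.x)
        design = _varpro_design(t, taus)
        coef = _ridge_amplitudes(design, v)
        cost = float(np.linalg.norm(design @ coef - v))
        candidates.append((cost, taus, coef))
    best_cost = min(c[0] for c in candidates)
    # among statistically indistinguishable minima prefer the most
    # parsimonious one: two nearly equal taus with huge cancelling
    # amplitudes fit no better than a well-separated pair with modest ones
    tol = best_cost * 1.02 + 1e-12
    near = [c for c in candidates if c[0] <= tol]
    cost, taus, coef = min(near, key=lambda c: np.max(np.abs(c[2][1:])))
    return taus, coef, cost


def membrane_time_constant(
    sweep: Sweep, config: AnalysisConfig = DEFAULT_CONFIG
) -> TauFit:
    """Membrane time constant from a hyperpolarizing (-300 pA) step.

    Fits V(t) = V_inf + A1 exp(-t/tau1) + A2 exp(-t/tau2) over the window
    from stimulus onset to the voltage minimum (capped by configuration),
    with both taus bounded in [0.1, 200] ms, starting from the
    single-exponential solution.  Returns the larger tau; if the double
    exponential fails to converge the single-exponential value is returned
    with a logged downgrade flag.
    """
    if sweep.step_amplitude >= 0:
        raise ValueError("membrane time constant needs a hyperpolarizing step")
    on = sweep.index_at(sweep.stim_onset)
    off = sweep.index_at(sweep.stim_offset)
    vmin_i = on + int(np.argmin(sweep.voltage[on:off]))
    cap = on + int(round(config.windows.tau_max_fit_ms / 1000.0
                         * sweep.sample_rate))
    end = min(vmin_i, cap)
    if end - on < 10:
        raise InsufficientDataError("fit window too short for tau")

    t_ms = 1000.0 * (sweep.time[on:end] - sweep.time[on])
    v = sweep.voltage[on:end]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            taus2, coef2, r2 = _fit_exponentials(t_ms, v, 2)
        except (np.linalg.LinAlgError, ValueError):
            log.warning("double-exponential fit failed; using single")
            try:
                taus1, coef1, r1 = _fit_exponentials(t_ms, v, 1)
            except (np.linalg.LinAlgError, ValueError) as exc:
                raise InsufficientDataError(f"exponential fit failed: {exc}")
            return TauFit(
                tau=float(taus1[0]),
                taus=(float(taus1[0]), float(taus1[0])),
                amplitudes=(float(coef1[1]), 0.0),
                offset=float(coef1[0]),
                residual_norm=r1,
                single_exponential_fallback=True,
            )

    # "use the higher value" refers to a real response component: one that
    # measurably moves the trace inside the fitted window.  A degenerate
    # second exponential chasing noise, or a time constant so slow that it
    # barely evolves before the window ends, contributes
    # |a| * (1 - exp(-T/tau)) and does not qualify below 5 % of the
    # deflection.
    deflection = float(np.ptp(v))
    amps = np.asarray(coef2[1:])
    T = t_ms[-1] if len(t_ms) else 1.0
    contrib = np.abs(amps) * (1.0 - np.exp(-T / np.asarray(taus2)))
    order = np.argsort(taus2)[::-1]
    significant = contrib >= _MIN_COMPONENT_FRACTION * deflection
    chosen = None
    for i in order:
        if significant[i]:
            chosen = int(i)
            break
    if chosen is None:
        chosen = int(np.argmax(contrib))
    return TauFit(
        tau=float(taus2[chosen]),
        taus=(float(taus2[0]), float(taus2[1])),
        amplitudes=(float(coef2[1]), float(coef2[2])),
        offset=float(coef2[0]),
        residual_norm=r2,
    )


@dataclass
class SagRebound:
    sag_ratio: float
    rebound: Optional[float]   # mV; None when a rebound AP intervenes
    v_baseline: float
    v_min: float
    v_ss: float
    v_max_post: Optional[float]


def sag_and_rebound(
    sweep: Sweep, config: AnalysisConfig = DEFAULT_CONFIG
) -> SagRebound:
    """Sag ratio and rebound from a hyperpolarizing step.

    sag = (V_baseline - V_ss) / (V_baseline - V_min), with V_baseline the
    mean over the pre-stimulus baseline window, V_min the post-onset
    minimum and V_ss the mean over the steady-state tail of the step.
    Rebound is the post-offset maximum minus baseline, searched over the
    post-stimulus window, and reported absent when a rebound AP falls in
    that window.
    """
    win = config.windows
    on = sweep.index_at(sweep.stim_onset)
    off = sweep.index_at(sweep.stim_offset)
    sr = sweep.sample_rate

    base_sl = sweep.slice_time(sweep.stim_onset - win.baseline_ms / 1000.0,
                               sweep.stim_onset)
    v_baseline = float(np.mean(sweep.voltage[base_sl]))
    v_min = float(np.min(sweep.voltage[on:off]))
    ss_sl = sweep.slice_time(sweep.stim_offset - win.steady_state_ms / 1000.0,
                             sweep.stim_offset)
    v_ss = float(np.mean(sweep.voltage[ss_sl]))

    if v_baseline <= v_min:
        raise UndefinedSagError(
            "no hyperpolarization below baseline; sag undefined"
        )
    sag = (v_baseline - v_ss) / (v_baseline - v_min)

    post_end = min(len(sweep.voltage),
                   off + int(round(win.post_stim_ms / 1000.0 * sr)))
    rebound: Optional[float] = None
    v_max_post: Optional[float] = None
    if post_end > off:
        t0, t1 = sweep.time[off], sweep.time[post_end - 1]
        post = Sweep(
            time=sweep.time[off:post_end],
            voltage=sweep.voltage[off:post_end],
            current=sweep.current[off:post_end],
            sample_rate=sr,
            stim_onset=t0,
            stim_offset=t1 + sweep.dt,
            sweep_kind="step",
        )
        has_rebound_ap = len(detect_action_potentials(post, config)) > 0
        v_max_post = float(np.max(sweep.voltage[off:post_end]))
        if not has_rebound_ap:
            rebound = v_max_post - v_baseline
    return SagRebound(
        sag_ratio=float(sag),
        rebound=rebound,
        v_baseline=v_baseline,
        v_min=v_min,
        v_ss=v_ss,
        v_max_post=v_max_post,
    )


def resting_potential(
    sweep: Sweep, config: AnalysisConfig = DEFAULT_CONFIG
) -> float:
    """Resting membrane potential: mean voltage of a spontaneous sweep.

    Logs a warning (spike-contaminated) when APs are present; the mean is
    still returned.
    """
    if sweep.sweep_kind != "spontaneous":
        raise ValueError("resting potential needs a spontaneous sweep")
    if np.any(np.abs(sweep.current) > 1e-9):
        raise ValueError("spontaneous sweep must carry zero injected current")
    if len(detect_action_potentials(sweep, config)) > 0:
        log.warning("spontaneous sweep contains spikes; V_m is contaminated")
    return float(np.mean(sweep.voltage))
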