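"""Whole-cell feature extraction: one CellRecording in, one feature row out.

Runs the full battery over a recording's protocol sweeps: quadratic
input-resistance fit over non-spiking steps, tau / sag / rebound from the
-300 pA step, resting potential from the spontaneous sweep, rheobase from
the 10-pA ramp, AP waveform features from the first AP of the first
spiking rheobase sweep, spike-train features from the +200 (or +210) pA
step, the F-I curve, ZAP resonance, and the QC verdict.  Missing protocol
pieces yield missing features, not failures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import AnalysisConfig, DEFAULT_CONFIG
from .exceptions import EntophysError, InsufficientDataError
from .firing import FICurvePoint, fi_curve, rheobase
from .passive import (
    average_sweeps,
    fit_input_resistance,
    membrane_time_constant,
    resting_potential,
    sag_and_rebound,
)
from .qc import QCResult, qc_filter
from .recording import CellRecording, Sweep
from .resonance import resonance_frequency
from .spikes import (
    APFeatures,
    TrainFeatures,
    ap_waveform_features,
    detect_action_potentials,
    spike_train_features,
)

log = logging.getLogger(__name__)


@dataclass
class CellFeatureSet:
    """All extracted scalar and per-AP/per-current features for one cell."""

    cell_id: str
    animal_id: str
    genotype: str
    region: str
    age_group: str = ""
    sex: str = ""
    setup: str = ""
    input_resistance: Optional[float] = None     # MOhm
    c_ar: Optional[float] = None                 # mV/pA^2
    tau: Optional[float] = None                  # ms
    sag_ratio: Optional[float] = None
    rebound: Optional[float] = None              # mV
    v_m: Optional[float] = None                  # mV
    rheobase: Optional[float] = None             # pA
    resonance_frequency: Optional[float] = None  # Hz
    is_resonant: Optional[bool] = None
    ap: Optional[APFeatures] = None
    train: Optional[TrainFeatures] = None
    fi: list[FICurvePoint] = field(default_factory=list)
    qc: Optional[QCResult] = None
    provenance: dict = field(default_factory=dict)

    def scalar_row(self) -> dict:
        """Flat dict for the cohort feature table (one row per cell)."""
        row = {
            "cell_id": self.cell_id,
            "animal_id": self.animal_id,
            "genotype": self.genotype,
            "region": self.region,
            "age_group": self.age_group,
            "sex": self.sex,
            "setup": self.setup,
            "input_resistance": self.input_resistance,
            "c_ar": self.c_ar,
            "tau": self.tau,
            "sag_ratio": self.sag_ratio,
            "rebound": self.rebound,
            "v_m": self.v_m,
            "rheobase": self.rheobase,
            "resonance_frequency": self.resonance_frequency,
            "ap_threshold": self.ap.threshold if self.ap else None,
            "ap_amplitude": self.ap.amplitude if self.ap else None,
            "ap_half_width": self.ap.half_width if self.ap else None,
            "fahp": self.ap.fahp if self.ap else None,
            "dap": self.ap.dap if self.ap else None,
            "isi1_over_isi2": (self.train.isi1_over_isi2
                               if self.train else None),
            "adaptation_ratio": (self.train.adaptation_ratio
                                 if self.train else None),
            "qc_included": self.qc.included if self.qc else None,
            "qc_reasons": ";".join(self.qc.reasons) if self.qc else "",
        }
        return row


def _steady_state_delta(sweep: Sweep, config: AnalysisConfig) -> float:
    win = config.windows
    base = sweep.slice_time(sweep.stim_onset - win.baseline_ms / 1000.0,
                            sweep.stim_onset)
    ss = sweep.slice_time(sweep.stim_offset - win.steady_state_ms / 1000.0,
                          sweep.stim_offset)
    return float(np.mean(sweep.voltage[ss]) - np.mean(sweep.voltage[base]))


def extract_cell_features(
    rec: CellRecording, config: AnalysisConfig = DEFAULT_CONFIG,
) -> CellFeatureSet:
    """Extract every feature the protocol supports for one cell."""
    out = CellFeatureSet(
        cell_id=rec.cell_id, animal_id=rec.animal_id,
        genotype=rec.genotype, region=rec.region,
        age_group=rec.age_group, sex=rec.sex, setup=rec.setup,
        provenance={"config": config.to_dict()},
    )

    steps = rec.steps()

    # input resistance from non-spiking steps
    points = []
    for s in steps:
        if s.step_amplitude == 0:
            continue
        if len(detect_action_potentials(s, config)) > 0:
            continue
        points.append((s.step_amplitude, _steady_state_delta(s, config)))
    try:
        fit = fit_input_resistance(points)
        out.input_resistance = fit.r_n0
        out.c_ar = fit.c_ar
        out.provenance["input_resistance_residual"] = fit.residual_norm
    except InsufficientDataError as exc:
        log.info("input resistance skipped for %s: %s", rec.cell_id, exc)

    # tau, sag, rebound from the -300 pA step (repeats averaged first)
    minus300_all = [s for s in rec.of_kind("step")
                    if abs(s.step_amplitude + 300.0) <= 0.5]
    minus300 = None
    if minus300_all:
        try:
            minus300 = average_sweeps(minus300_all)
        except ValueError:
            minus300 = minus300_all[0]
    if minus300 is not None:
        try:
            tau_fit = membrane_time_constant(minus300, config)
            out.tau = tau_fit.tau
            out.provenance["tau_fit"] = {
                "taus": tau_fit.taus, "amplitudes": tau_fit.amplitudes,
                "residual": tau_fit.residual_norm,
                "single_exponential_fallback":
                    tau_fit.single_exponential_fallback,
            }
        except EntophysError as exc:
            log.info("tau skipped for %s: %s", rec.cell_id, exc)
        try:
            sr = sag_and_rebound(minus300, config)
            out.sag_ratio = sr.sag_ratio
            out.rebound = sr.rebound
        except EntophysError as exc:
            log.info("sag skipped for %s: %s", rec.cell_id, exc)

    # resting potential
    spont = rec.of_kind("spontaneous")
    if spont:
        out.v_m = resting_potential(spont[0], config)

    # rheobase + first-AP waveform
    rheo_sweeps = rec.rheobase_steps()
    if rheo_sweeps:
        rb = rheobase(rheo_sweeps, config)
        out.rheobase = rb.rheobase
        out.provenance["rheobase_max_tested"] = rb.max_tested
        if rb.reached:
            first = rheo_sweeps[rb.sweep_index]
            try:
                out.ap = ap_waveform_features(first, 0, region=rec.region,
                                              config=config)
            except (EntophysError, ValueError, IndexError) as exc:
                log.info("AP features skipped for %s: %s", rec.cell_id, exc)

    # spike train from +200/210 pA
    train_sweep = None
    for amp in (200.0, 210.0):
        try:
            train_sweep = rec.step_at(amp)
            break
        except KeyError:
            continue
    if train_sweep is not None:
        out.train = spike_train_features(train_sweep, config)

    # F-I curve
    positive = [s for s in steps if s.step_amplitude > 0]
    if positive:
        out.fi = fi_curve(positive, config)

    # resonance
    zaps = rec.of_kind("zap")
    if zaps:
        try:
            res = resonance_frequency(zaps[0], config)
            out.resonance_frequency = res.resonance_frequency
            out.is_resonant = res.is_resonant
        except EntophysError as exc:
            log.info("resonance skipped for %s: %s", rec.cell_id, exc)

    out.qc = qc_filter(
        v_m=out.v_m if out.v_m is not None else float("nan"),
        ap_amplitude=(out.ap.amplitude if out.ap is not None
                      else float("nan")),
        bridge_balance=rec.bridge_balance,
        config=config,
    )
    return out
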