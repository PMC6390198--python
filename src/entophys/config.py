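"""Analysis configuration.

All windows, thresholds and kernel sizes used anywhere in the pipeline live
in one serializable object so that every output file can carry the exact
settings it was produced with.  Defaults follow common current-clamp and
slice-imaging practice; each field is documented with its unit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any


@dataclass
class SpikeConfig:
    """Action-potential detection criteria.

    An AP onset is a sample where dV/dt first exceeds ``dvdt_threshold``
    (mV/ms, i.e. V/s); the spike peak must exceed ``min_peak`` and peaks
    closer than ``refractory_ms`` are merged (the earlier one wins).
    """

    dvdt_threshold: float = 20.0   # mV/ms
    min_peak: float = -10.0        # mV
    refractory_ms: float = 2.0
    peak_search_ms: float = 5.0    # window after onset to locate the peak


@dataclass
class WindowConfig:
    """Measurement windows for passive and AP waveform features (ms)."""

    baseline_ms: float = 100.0        # pre-stimulus mean for V_baseline
    steady_state_ms: float = 200.0    # tail of the step for V_ss
    post_stim_ms: float = 500.0       # rebound / post-step AHP search
    fahp_ms: float = 5.0              # fAHP search after the AP peak
    dap_ms: float = 20.0              # DAP search after the fAHP
    threshold_search_ms: float = 5.0  # pre-peak window for AP threshold
    smooth_ms: float = 0.6            # local-polynomial smoothing window
    tau_max_fit_ms: float = 500.0     # cap on the tau fit window (the fit
    #   normally ends at the voltage minimum of the hyperpolarizing step)


@dataclass
class ResonanceConfig:
    """ZAP impedance analysis settings."""

    band_hz: tuple[float, float] = (0.5, 20.0)
    smooth_hz: float = 0.5            # moving-average width on |Z|(f)
    edge_tol_hz: float = 0.25         # argmax within this of the lower edge
    #   -> classified as non-resonant
    min_q: float = 1.05               # peak must beat the low-frequency
    #   impedance by this factor to count as resonance


@dataclass
class VSDIConfig:
    """VSDI quantification settings."""

    spatial_kernel: int = 3           # box kernel side, pixels (odd)
    temporal_window: int = 5          # Savitzky-Golay window, frames (odd)
    temporal_order: int = 3           # cubic temporal filter
    threshold_pct: float = 0.05       # activated-pixel threshold, % dF/F
    ppr_interval_ms: float = 25.0
    ppr_window_ms: float = 20.0       # amplitude search after each pulse
    sign_flip: bool = True            # depolarization-positive convention


@dataclass
class QCConfig:
    """Cell inclusion rules (strict inequalities, as printed)."""

    max_vm: float = -57.0             # excluded when V_m > max_vm
    min_ap_amplitude: float = 75.0    # excluded when amplitude < this
    max_bridge_balance: float = 22.0  # MOhm; excluded when above


@dataclass
class AnalysisConfig:
    spike: SpikeConfig = field(default_factory=SpikeConfig)
    windows: WindowConfig = field(default_factory=WindowConfig)
    resonance: ResonanceConfig = field(default_factory=ResonanceConfig)
    vsdi: VSDIConfig = field(default_factory=VSDIConfig)
    qc: QCConfig = field(default_factory=QCConfig)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_json(self, **kwargs: Any) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "AnalysisConfig":
        def build(klass, sub):
            kwargs = dict(sub)
            if klass is ResonanceConfig and "band_hz" in kwargs:
                kwargs["band_hz"] = tuple(kwargs["band_hz"])
            return klass(**kwargs)

        return cls(
            spike=build(SpikeConfig, d.get("spike", {})),
            windows=build(WindowConfig, d.get("windows", {})),
            resonance=build(ResonanceConfig, d.get("resonance", {})),
            vsdi=build(VSDIConfig, d.get("vsdi", {})),
            qc=build(QCConfig, d.get("qc", {})),
        )

    @classmethod
    def from_json(cls, s: str) -> "AnalysisConfig":
        return cls.from_dict(json.loads(s))


DEFAULT_CONFIG = AnalysisConfig()
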