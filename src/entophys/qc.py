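"""Cell-level quality control.

Cells are excluded when the resting potential is depolarized beyond
-57 mV, the AP amplitude is below 75 mV, or the bridge balance exceeds
22 MOhm (all strict inequalities).  Putative interneurons are excluded by
experimenter judgment upstream and enter here only as a manual flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .config import AnalysisConfig, DEFAULT_CONFIG

REASONS = (
    "depolarized_Vm",
    "low_AP_amplitude",
    "high_bridge_balance",
    "putative_interneuron_flagged_manually",
)


@dataclass
class QCResult:
    included: bool
    reasons: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        assert self.included == (len(self.reasons) == 0)


def qc_filter(
    v_m: float,
    ap_amplitude: float,
    bridge_balance: float,
    putative_interneuron: bool = False,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> QCResult:
    """Apply the inclusion rules; reasons enumerate every violated rule.

    NaN inputs do not trigger the corresponding rule (a missing value is
    not evidence of a violation); order of evaluation is fixed and the
    result is idempotent in its inputs.
    """
    qc = config.qc
    reasons: list[str] = []
    if not math.isnan(v_m) and v_m > qc.max_vm:
        reasons.append("depolarized_Vm")
    if not math.isnan(ap_amplitude) and ap_amplitude < qc.min_ap_amplitude:
        reasons.append("low_AP_amplitude")
    if not math.isnan(bridge_balance) and bridge_balance > qc.max_bridge_balance:
        reasons.append("high_bridge_balance")
    if putative_interneuron:
        reasons.append("putative_interneuron_flagged_manually")
    return QCResult(included=not reasons, reasons=tuple(reasons))
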