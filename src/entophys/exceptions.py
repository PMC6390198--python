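"""Structured errors raised by the analysis pipeline.

Every error that corresponds to a defined failure mode of an operation
(malformed input, insufficient data, an exclusion rule firing) has its own
class so callers can react to it without string matching.
"""


class EntophysError(Exception):
    """Base class for all package errors."""


class NonUniformSamplingError(EntophysError):
    """Sweep time base is not uniformly sampled within tolerance."""


class InsufficientDataError(EntophysError):
    """Too few data points (or a rank-deficient design) for a fit."""


class UndefinedSagError(EntophysError):
    """Sag ratio undefined: the step did not hyperpolarize the cell."""


class NotEstimableError(EntophysError):
    """Quantity cannot be estimated from this trace (e.g. spikes in a ZAP)."""


class UndefinedJunctionError(EntophysError):
    """Junction potential undefined: no charged species in a solution."""


class UndefinedPPRError(EntophysError):
    """Paired-pulse ratio undefined: first-pulse amplitude is not positive."""


class EmptyROIError(EntophysError):
    """ROI contains no pixels."""


class DimensionMismatchError(EntophysError):
    """Array geometry disagrees with its metadata or a sibling array."""


class ManifestError(EntophysError):
    """Manifest fails validation (missing file, duplicate id, bad genotype)."""


class ConvergenceError(EntophysError):
    """All candidate model fits failed to converge."""


class SimulationError(EntophysError):
    """Numerical integration of a model cell became unstable."""
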