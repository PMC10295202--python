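"""Exception hierarchy for dotpulse."""


class DotPulseError(Exception):
    """Base class for all dotpulse errors."""


class FormatError(DotPulseError):
    """Input file is malformed (missing columns, bad delimiter, ...)."""


class EmptyTraceError(DotPulseError):
    """Fewer than two valid samples after cleaning."""


class NonUniformError(DotPulseError):
    """Operation requires a uniformly sampled trace; resample first."""


class UndefinedCorrelationError(DotPulseError):
    """Covariate has zero variance; correlation is undefined."""


class NotApplicableError(DotPulseError):
    """Estimator preconditions not met for this pulse type."""


class SingularRecoveryError(DotPulseError):
    """Recovery endpoint at or above saturation; log term is singular."""


class DegeneratePulseError(DotPulseError):
    """Pulse too short or malformed to analyse."""


class IntegrationError(DotPulseError):
    """ODE integration failed; carries the last valid state."""

    def __init__(self, message, last_state=None):
        super().__init__(message)
        self.last_state = last_state
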