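"""Exception hierarchy for vbsa."""


class VbsaError(Exception):
    """Base class for all vbsa errors."""


class ModelParseError(VbsaError):
    """Raised when a model file cannot be parsed; carries line/context info."""


class ModelValidationError(VbsaError):
    """Raised when a parsed model violates a structural invariant."""


class IntegrationError(VbsaError):
    """Raised when the ODE solver fails to produce a valid trajectory."""


class DegenerateResponseError(VbsaError):
    """Raised when a response characteristic (D, I, or S) is undefined,
    e.g. an identically-zero trajectory or a zero-width transient."""


class EvaluationError(VbsaError):
    """Raised when a response evaluation fails; carries the offending factor
    vector so the failing sample can be identified."""

    def __init__(self, message, w=None):
        super().__init__(message)
        self.w = w


class FixtureUnavailableError(VbsaError):
    """Raised when an optional model fixture (e.g. the transcribed MAPK
    cascade parameter set) is not present in the installation."""


class UndefinedIndicesError(VbsaError):
    """Raised when sensitivity indices are requested for a decomposition
    with zero second-order variance portion."""


class ConfigError(VbsaError):
    """Raised for invalid analysis configurations."""
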