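"""Exception hierarchy shared by all analysis stages."""


class AlbindError(Exception):
    """Base class for all package errors."""


class InvalidInputError(AlbindError, ValueError):
    """Input violates a documented precondition (negative intensity, F = 0, ...)."""


class InsufficientDataError(AlbindError):
    """Too few points/temperatures/channels for the requested fit."""


class InsufficientEvidenceError(AlbindError):
    """Not enough independent observations to run a rule-based classification."""


class NoPeakError(AlbindError):
    """Spectrum or grid has no interior maximum to report."""


class ParseError(AlbindError):
    """A data file does not conform to the documented CSV dialect."""


class FitFailureError(AlbindError):
    """Non-linear fit failed to converge for every candidate model order."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class UnclassifiableError(AlbindError):
    """Thermodynamic signs fall outside the sign-based force taxonomy."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class AlbindWarning(UserWarning):
    """Base warning category (high absorbance, intercept drift, poor fit, ...)."""
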