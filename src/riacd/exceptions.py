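"""Exception hierarchy shared across the package."""


class RiacdError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RiacdError):
    """Input file could not be parsed (e.g. bad timestamp)."""


class IntegrityError(RiacdError):
    """Input violates uniqueness or consistency requirements."""


class ValidationError(RiacdError):
    """A value is outside its admissible domain."""


class DegenerateHourError(RiacdError):
    """An hour-of-day has a zero across-day average; division undefined."""


class ConfigurationError(RiacdError):
    """Inconsistent configuration (mismatched thresholds, bad matrix, ...)."""


class InsufficientDataError(RiacdError):
    """Too few observations for the requested operation."""


class NonstationarityError(RiacdError):
    """Parameters violate the weak-stationarity condition."""


class DegenerateDataError(RiacdError):
    """Input has no variation (e.g. constant durations)."""


class ConvergenceError(RiacdError):
    """No optimizer restart converged; carries diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


class StateError(RiacdError):
    """Forecast state incomplete."""
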