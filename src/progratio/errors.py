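"""Exception hierarchy for the progressive-ratio analysis pipeline."""


class ProgRatioError(Exception):
    """Base class for all package-specific errors."""


class ArgumentError(ProgRatioError, ValueError):
    """An argument violated a precondition (negative time, empty schedule, ...)."""


class IntegrityError(ProgRatioError):
    """An event log is inconsistent with the schedule it claims to realise."""


class ParseError(ProgRatioError):
    """A serialized event log could not be parsed; carries the offending line."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class NoBreakpointError(ProgRatioError):
    """No breakpoint is defined for a session (no completed ratio)."""


class FitError(ProgRatioError):
    """Model fitting could not be attempted (too few usable data points)."""


class ConvergenceError(ProgRatioError):
    """All optimisation starts failed to converge."""


class UndefinedR2Error(ProgRatioError):
    """R-squared is undefined because the total sum of squares is zero."""


class DesignError(ProgRatioError):
    """An experimental design is invalid for the requested analysis."""
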