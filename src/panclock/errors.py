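"""Exception hierarchy shared across the package."""


class PanclockError(Exception):
    """Base class for package errors."""


class ConfigurationError(PanclockError, ValueError):
    """A simulator or analysis configuration is internally inconsistent."""


class ValidationError(PanclockError, ValueError):
    """Input data violate a contract (values out of range, missing metadata)."""


class FitError(PanclockError, RuntimeError):
    """A model could not be fit (too few samples, degenerate design)."""


class ClockParseError(PanclockError, ValueError):
    """A serialized clock/predictor file is malformed."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
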