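"""Exception hierarchy shared across the package.

Index functions raise :class:`InsufficientDataError` when a window cannot
support the computation; trace builders catch it and record a missing value
instead, so a short window never silently becomes a zero.
"""


class FetalHRVError(Exception):
    """Base class for all package errors."""


class ConfigError(FetalHRVError):
    """Invalid configuration (window specs, generator settings, CLI options)."""


class ParseError(FetalHRVError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(FetalHRVError):
    """Data violating a physiologic or structural invariant."""


class InsufficientDataError(FetalHRVError):
    """Too little data in a window for the requested index."""


class OutOfRangeError(FetalHRVError):
    """Requested window or time lies outside the record."""
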