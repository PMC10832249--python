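"""Exception hierarchy.

All package errors derive from :class:`PathpredError` so callers (and the
CLI) can distinguish domain failures from programming errors.
"""


class PathpredError(Exception):
    """Base class for all pathpred errors."""


class ValidationError(PathpredError, ValueError):
    """A domain object violates one of its invariants."""


class ParseError(ValidationError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConsistencyError(PathpredError, ValueError):
    """Two artifacts that must share provenance (database fingerprint,
    feature layout) do not match."""


class ConfigError(PathpredError, ValueError):
    """An invalid configuration value."""
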