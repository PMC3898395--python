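"""Exception hierarchy for glucofet.

All library errors derive from :class:`GlucofetError`; most are also
``ValueError`` subclasses so generic callers can catch them idiomatically.
"""

from __future__ import annotations


class GlucofetError(Exception):
    """Base class for all glucofet errors."""


class InvalidParameterError(GlucofetError, ValueError):
    """A physical or configuration parameter violates its invariant."""


class DomainError(InvalidParameterError):
    """An operation was evaluated outside its mathematical domain."""


class OutOfRangeError(InvalidParameterError):
    """A value lies outside the range of an invertible law."""


class InsufficientDataError(GlucofetError, ValueError):
    """Too few data points to perform the requested estimate."""


class AlignmentError(GlucofetError, ValueError):
    """Two datasets do not share identical (condition, drain-voltage) keys."""

    def __init__(self, message: str, missing_pairs=None):
        super().__init__(message)
        self.missing_pairs = list(missing_pairs) if missing_pairs else []


class NormalizationError(GlucofetError, ValueError):
    """Normalized RMS is undefined (zero measured mean current)."""


class IdentifiabilityError(GlucofetError, ValueError):
    """The requested free parameters cannot be identified from the data."""


class ParseError(GlucofetError, ValueError):
    """A CSV or configuration file failed to parse; carries location info."""

    def __init__(self, message: str, *, path=None, line=None, row=None):
        loc = []
        if path is not None:
            loc.append(str(path))
        if line is not None:
            loc.append(f"line {line}")
        if row is not None:
            loc.append(f"row {row}")
        prefix = ":".join(loc)
        super().__init__(f"{prefix}: {message}" if prefix else message)
        self.path = path
        self.line = line
        self.row = row


class ConfigError(ParseError):
    """A run-configuration file is malformed or contains unknown keys."""
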