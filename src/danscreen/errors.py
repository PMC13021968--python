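"""Exception hierarchy for the triage pipeline.

Every stage raises a subclass of :class:`DanScreenError`, so callers (and the
CLI) can distinguish malformed inputs (exit code 2) from statistical
preconditions that the data cannot satisfy (exit code 3).
"""


class DanScreenError(Exception):
    """Base class for all pipeline errors."""


class FormatError(DanScreenError):
    """A required column or field is missing from an input table."""


class ParseError(DanScreenError):
    """A value could not be parsed or violates a field invariant."""


class ValidationError(DanScreenError):
    """Cross-record consistency failure (e.g. catalog entry for unknown gene)."""


class MissingReferenceError(DanScreenError):
    """No control observations exist for the requested reference."""


class DegenerateReferenceError(DanScreenError):
    """A control reference is zero or negative, so ratios are undefined."""


class UndefinedPIError(DanScreenError):
    """A performance index is undefined (no flies counted)."""


class MissingDataError(DanScreenError):
    """A record has no usable measurements."""


class NormalizationError(DanScreenError):
    """Housekeeping normalization is impossible (zero housekeeping count)."""


class InsufficientDataError(DanScreenError):
    """Too few observations for the requested statistical test."""


class ProtocolError(DanScreenError):
    """A stimulus protocol is inconsistent with the recording it describes."""
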