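"""Exception hierarchy shared across the package."""


class GlennPVRError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(GlennPVRError):
    """A required column is missing or the header does not match the schema."""


class TableParseError(GlennPVRError):
    """A cell could not be parsed; message names the row and column."""


class DomainError(GlennPVRError, ValueError):
    """An argument is outside the physically meaningful domain."""


class AlignmentError(GlennPVRError):
    """Two waveforms are not on the same temporal grid."""


class SingularCircuitError(GlennPVRError):
    """The circuit has no unique solution (e.g. both branch totals zero)."""


class InsufficientDataError(GlennPVRError):
    """Too few observations for the requested summary or test."""


class UndefinedICCError(GlennPVRError):
    """ICC is undefined (no between-subject variance)."""
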