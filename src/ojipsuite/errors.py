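"""Typed exception hierarchy.

Every malformed input raises one of these; nothing is silently coerced.
"""


class OjipError(Exception):
    """Base class for all package errors."""


class FormatError(OjipError):
    """A delimited-text file violates the documented dialect (names the row)."""


class SchemaError(OjipError):
    """A required column is missing or mistyped."""


class ValidationError(OjipError):
    """A record violates a domain invariant (negative absorbance, zero mass, ...)."""


class ConfigurationError(OjipError):
    """An analysis or generator configuration is internally inconsistent."""


class CoverageError(OjipError):
    """A trace does not cover the time span an operation needs."""


class DegenerateTransientError(OjipError):
    """A prompt-fluorescence transient has no variable fluorescence (F_v <= 0)."""


class InvalidSignalError(OjipError):
    """A signal value is unusable (e.g. non-positive MR_o reference)."""


class FitError(OjipError):
    """A least-squares fit failed to converge; carries diagnostics in args."""


class InsufficientReplicatesError(OjipError):
    """A statistical operation needs at least two replicates per group."""
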