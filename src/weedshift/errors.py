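"""Exception hierarchy for weedshift."""


class WeedshiftError(Exception):
    """Base class for all package errors."""


class SchemaError(WeedshiftError):
    """A required column or field is missing from an input file."""


class ValidationError(WeedshiftError):
    """Input rows violate a declared invariant; offending rows are listed."""

    def __init__(self, message, rows=None):
        super().__init__(message)
        self.rows = list(rows) if rows is not None else []


class FormatError(WeedshiftError):
    """A file could not be parsed in its declared format."""


class InsufficientDataError(WeedshiftError):
    """Not enough observations to run the requested analysis."""


class NumericalError(WeedshiftError):
    """A numerical routine failed (singular matrix, non-finite likelihood)."""
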