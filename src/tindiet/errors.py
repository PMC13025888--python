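"""Exception hierarchy shared across the pipeline."""


class TindietError(Exception):
    """Base class for all package errors."""


class SchemaError(TindietError):
    """An input table is missing columns or has an unrecognised layout."""


class DataValidationError(TindietError):
    """A row violates a domain invariant; the message names row and column."""


class DomainError(TindietError):
    """An argument is outside the mathematical domain of an operation."""


class CalibrationError(TindietError):
    """Summary targets cannot be represented by the generator's mixture."""
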