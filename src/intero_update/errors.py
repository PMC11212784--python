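"""Exception types shared across the pipeline."""


class InteroUpdateError(Exception):
    """Base class for all package errors."""


class ConfigurationError(InteroUpdateError):
    """A configuration object violates its invariants (names the field)."""


class DomainError(InteroUpdateError):
    """An input violates a mathematical precondition of an operation."""


class UndefinedUpdateError(DomainError):
    """Both precision weights are zero, so the belief update is undefined."""


class InsufficientDataError(InteroUpdateError):
    """Too few valid participants remain for the requested analysis."""


class SchemaError(InteroUpdateError):
    """A data table is missing required columns or has malformed values."""
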