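"""Typed exceptions shared across the pipeline stages."""


class TrflpError(Exception):
    """Base class for all package errors."""


class FormatError(TrflpError):
    """A file or record violates its expected format."""


class SchemaError(TrflpError):
    """A delimited table is missing required columns."""


class EmptyInputError(TrflpError):
    """An input that must contain data is empty."""


class UsageError(TrflpError):
    """An operation was called with incompatible or invalid arguments."""


class DomainError(TrflpError):
    """A numeric argument is outside the mathematical domain of an operation."""


class EmptyProfileError(TrflpError):
    """A peak profile with zero total area where signal is required."""


class GenerationError(TrflpError):
    """The synthetic generator could not satisfy its constraints."""
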