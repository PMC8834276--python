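"""Exception hierarchy shared across the package."""


class EtccError(Exception):
    """Base class for all package errors."""


class SchemaError(EtccError):
    """A tabular input file does not match the expected column schema."""


class RecordValidationError(EtccError, ValueError):
    """A record violates one of its type invariants."""


class DomainError(EtccError, ValueError):
    """An operation received an argument outside its mathematical domain."""


class ConfigurationError(EtccError):
    """Required configuration (e.g. an hour-based denominator) is missing."""


class UsageError(EtccError):
    """An operation was called inconsistently (unknown mode, bad plan, ...)."""
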