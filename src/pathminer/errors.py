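"""Shared exception types."""


class PathminerError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PathminerError):
    """An invalid configuration field; the message names the field."""


class SchemaError(PathminerError):
    """A required column is missing from an input table; the message names it."""


class ArgumentError(PathminerError):
    """An operation received an invalid argument."""


class ShapeError(PathminerError):
    """Array shapes or feature indices are incompatible."""


class SizeError(PathminerError):
    """An input exceeds a guard intended to keep exhaustive computation feasible."""
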