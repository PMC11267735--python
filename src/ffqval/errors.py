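"""Exception types shared across the package."""


class FFQValError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FFQValError):
    """A table, mapping or config file is invalid or incomplete."""


class RecordValidationError(FFQValError):
    """An input record violates the schema it claims to follow."""


class CoverageError(ConfigurationError):
    """A lookup table does not cover a key needed by the data."""
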