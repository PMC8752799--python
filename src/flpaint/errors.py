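"""Exception hierarchy shared across the pipeline."""


class FLPaintError(Exception):
    """Base class for all package errors."""


class InvalidConfigurationError(FLPaintError, ValueError):
    """A configuration value violates its documented constraints."""


class FormatError(FLPaintError, IOError):
    """A file is not a readable photon-stream / table of the expected schema."""


class SchemaError(FormatError):
    """A table is missing mandatory columns or carries an unknown schema version."""
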