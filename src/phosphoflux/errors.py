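"""Exception types shared across the pipeline."""


class PhosphofluxError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PhosphofluxError, ValueError):
    """Invalid configuration or parameter combination."""


class SchemaError(PhosphofluxError, ValueError):
    """Input table is missing required columns or has malformed values."""


class EmptyInputError(PhosphofluxError, ValueError):
    """An operation received no usable data."""


class UnusableTraceError(PhosphofluxError, ValueError):
    """A fluorescence trace cannot be corrected/normalized."""


class InsufficientDataError(PhosphofluxError, ValueError):
    """Too few observations for the requested statistic."""
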