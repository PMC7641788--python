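"""Exception hierarchy.

``DataError`` subclasses signal problems with the input tables (exit code 1
in the CLI); ``ConfigError`` signals an invalid configuration (exit code 2).
"""


class NutripairError(Exception):
    """Base class for all package-specific errors."""


class DataError(NutripairError):
    """A problem with the content of an input table."""


class SchemaError(DataError):
    """A required column is missing or misnamed."""


class ValidationError(DataError):
    """A cell value violates an invariant (e.g. a negative amount)."""


class DegenerateDataError(DataError):
    """Data too degenerate for the requested statistic (e.g. zero variance)."""


class ConfigError(NutripairError):
    """Invalid configuration values."""
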