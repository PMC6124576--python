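"""Exception hierarchy.

ConfigurationError maps to CLI exit code 2, DataError (and subclasses) to 3.
"""


class EpiconserveError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EpiconserveError):
    """Invalid configuration value or missing configuration file."""


class DataError(EpiconserveError):
    """Invalid input data."""


class DataFormatError(DataError):
    """Malformed file content (ragged rows, missing columns, bad values)."""


class ValidationError(DataError):
    """Data that parses but violates a contract (duplicates, empty groups)."""
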