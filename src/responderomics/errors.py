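"""Exception hierarchy shared across the package.

``ConfigError`` maps to CLI exit code 2 and ``DataError`` (and its
subclasses) to exit code 3.
"""


class ResponderomicsError(Exception):
    """Base class for all package errors."""


class ConfigError(ResponderomicsError):
    """Invalid parameters, configuration files, or option combinations."""


class DataError(ResponderomicsError):
    """Invalid or inconsistent input data."""


class FormatError(DataError):
    """Malformed on-disk artifact; message names the offending line/column."""


class DesignError(DataError):
    """Sample layout incompatible with the requested contrast or split."""
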