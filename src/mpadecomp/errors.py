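"""Exception hierarchy shared across the package.

``ConfigError`` maps to CLI exit code 2, ``DataError`` (and its subclass
``ParseError``) to exit code 3.
"""


class MpaError(Exception):
    """Base class for all package errors."""


class ConfigError(MpaError):
    """Invalid configuration: bad parameter values, missing required options."""


class DataError(MpaError):
    """Invalid or inconsistent input data."""


class ParseError(DataError):
    """A file could not be parsed; the message names the offending line/row."""
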