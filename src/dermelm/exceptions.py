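"""Exception hierarchy shared across the package.

The CLI maps these onto process exit codes (config 2, data 3, numerical 4).
"""


class DermelmError(Exception):
    """Base class for all package errors."""


class ConfigError(DermelmError, ValueError):
    """Invalid configuration or parameter value."""


class DataError(DermelmError, ValueError):
    """Invalid, degenerate or missing input data."""


class NumericalError(DermelmError, ArithmeticError):
    """A numerical routine failed to produce a usable result."""
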