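"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes (config errors 2, data errors 3,
anything else 4).
"""


class DreamchipError(Exception):
    """Base class for all package errors."""


class ConfigError(DreamchipError):
    """Invalid configuration, parameters, or argument combinations."""


class DataError(DreamchipError):
    """Malformed or inconsistent input data."""
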