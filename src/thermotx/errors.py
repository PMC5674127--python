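"""Exception hierarchy shared across the pipeline stages.

The CLI maps these onto exit codes: ConfigError -> 2, DataError -> 3,
NumericalError -> 4.
"""


class ThermotxError(Exception):
    """Base class for all package errors."""


class ConfigError(ThermotxError):
    """Invalid configuration (bad parameter value, unknown key, missing file)."""


class DataError(ThermotxError):
    """Malformed or inconsistent input data."""


class NumericalError(ThermotxError):
    """A numerical procedure failed (non-convergence, degenerate input)."""
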