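"""Exception hierarchy.

Input/configuration problems map to CLI exit code 1, numerical problems
(including MCMC divergence) to exit code 2.
"""


class DpprsError(Exception):
    """Base class for all package errors."""


class InputError(DpprsError):
    """Bad or empty input data (files, tables, counts)."""


class ConfigError(DpprsError):
    """Invalid configuration value (flags, thresholds, column maps)."""


class NumericalError(DpprsError):
    """A computation produced non-finite or unusable values."""


class DivergenceError(NumericalError):
    """The MCMC divergence guard tripped (max |beta| exceeded the bound)."""
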