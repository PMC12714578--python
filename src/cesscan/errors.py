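"""Exception hierarchy shared across the package.

Two broad failure classes are distinguished so the CLI can map them to
exit codes: configuration problems (exit 2) and malformed/inconsistent
data (exit 3).
"""


class CesScanError(Exception):
    """Base class for all package errors."""


class ConfigError(CesScanError):
    """Invalid configuration: bad parameter values, mixture weights, paths."""


class DataError(CesScanError):
    """Malformed or internally inconsistent input data."""


class ConvergenceError(CesScanError):
    """An optimizer failed to converge; carries diagnostics in args."""
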