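"""Exception hierarchy.

Every error raised on purpose by this package derives from ThermoQtlError so
callers (and the CLI) can distinguish expected failure modes from bugs.
"""


class ThermoQtlError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(ThermoQtlError, ValueError):
    """A user-supplied parameter is outside its documented domain."""


class DimensionError(ThermoQtlError, ValueError):
    """Array/table shapes do not line up."""


class LayoutError(ThermoQtlError, ValueError):
    """Trial layout cannot be constructed (e.g. grid capacity exceeded)."""


class LookupError_(ThermoQtlError, KeyError):
    """An entry/genotype id referenced by one table is missing from another."""


class DomainError(ThermoQtlError, ValueError):
    """A numeric input is outside the mathematical domain of an operation."""


class EmptyRoiError(ThermoQtlError, ValueError):
    """Segmentation produced an empty foreground, or an all-NaN image."""


class ConvergenceError(ThermoQtlError, RuntimeError):
    """An iterative solver failed to converge; carries the iteration trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


class RankError(ThermoQtlError, ValueError):
    """A design matrix is singular / rank deficient."""


class DataError(ThermoQtlError, ValueError):
    """Malformed input data (bad dosage values, unsorted map, ...)."""


class ConfigError(ThermoQtlError, ValueError):
    """Pipeline configuration fails validation."""
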