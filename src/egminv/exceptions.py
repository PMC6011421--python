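"""Exception hierarchy for egminv."""


class EgminvError(Exception):
    """Base class for all egminv errors."""


class GeometryError(EgminvError, ValueError):
    """Invalid geometry, e.g. non-positive catchment height z0."""


class GridError(EgminvError, ValueError):
    """Degenerate or inconsistent discretization grid."""


class DimensionMismatchError(EgminvError, ValueError):
    """Array shapes or grids do not match."""


class ConfigurationError(EgminvError, ValueError):
    """Invalid configuration value or unknown option."""


class ParameterError(EgminvError, ValueError):
    """Solver parameter outside its valid range."""


class IllConditioningError(EgminvError, RuntimeError):
    """Linear system numerically singular; regularization required."""


class ConvergenceError(EgminvError, RuntimeError):
    """Iterative solver failed to converge within its iteration budget.

    Carries the last iterate in ``last_iterate`` for diagnostics.
    """

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class SolverError(EgminvError, RuntimeError):
    """Underlying optimization engine failed."""


class DomainError(EgminvError, ValueError):
    """Requested position lies outside the tissue patch."""


class UndefinedSNRError(EgminvError, ValueError):
    """Signal power is zero, so a finite SNR cannot be realized."""
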