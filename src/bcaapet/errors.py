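"""Exception hierarchy shared across the package."""


class BcaapetError(Exception):
    """Base class for all package-specific errors."""


class InvalidGridError(BcaapetError, ValueError):
    """Time grid is empty, non-uniform, or does not start at zero."""


class InvalidInputError(BcaapetError, ValueError):
    """Input-function values are negative or otherwise unusable."""


class UndefinedRatioError(BcaapetError, ZeroDivisionError):
    """Macro-parameter ratio undefined (k2 + k3 == 0)."""


class CoverageError(BcaapetError, ValueError):
    """Frame schedule extends beyond the simulated time grid."""


class InsufficientDataError(BcaapetError, ValueError):
    """Not enough late frames (or data points) for the requested estimate."""


class ConfigurationError(BcaapetError, ValueError):
    """Unknown scheme id or out-of-range configuration value."""


class NonConvergenceError(BcaapetError, RuntimeError):
    """All fit restarts failed; carries the best-effort result."""

    def __init__(self, message, best_result=None):
        super().__init__(message)
        self.best_result = best_result


class AlignmentError(BcaapetError, ValueError):
    """Voxel grids or masks do not share a common shape."""


class EmptyVOIError(BcaapetError, ValueError):
    """Mask selects no voxels."""


class VOITooSmallError(BcaapetError, ValueError):
    """VOI volume below the configured minimum (default 5.0 mL)."""


class ScheduleError(BcaapetError, ValueError):
    """Frame count mismatch between dynamic volumes and schedule."""


class LayoutError(BcaapetError, ValueError):
    """Phantom regions overlap or fall outside the volume."""


class InvalidParamsError(BcaapetError, ValueError):
    """Parametric input-function coefficients violate their constraints."""


class InsufficientGroupError(BcaapetError, ValueError):
    """A comparison group has fewer than two observations."""


class UndefinedCorrelationError(BcaapetError, ValueError):
    """Correlation undefined (constant vector)."""
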