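"""Exception hierarchy.

Every error raised by the package derives from :class:`TwinPlatError` so
callers can catch one type at pipeline boundaries.
"""


class TwinPlatError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(TwinPlatError, ValueError):
    """A parameter is outside its valid range (e.g. cutoff above Nyquist)."""


class InsufficientDataError(TwinPlatError, ValueError):
    """A series is too short for the requested operation."""


class GridMismatchError(TwinPlatError, ValueError):
    """Two series that must share a sampling grid do not."""


class SyncFailureError(TwinPlatError, RuntimeError):
    """Sync-channel edge detection failed (zero or multiple rising edges)."""


class MetricUndefinedError(TwinPlatError, RuntimeError):
    """A tracking metric cannot be computed (threshold never reached)."""


class DivergenceError(TwinPlatError, RuntimeError):
    """A simulated trajectory diverged (unstable parameterization)."""


class InfeasibleTargetError(TwinPlatError, ValueError):
    """Channel decomposition target requires negative corner loads."""


class IdentificationError(TwinPlatError, RuntimeError):
    """System identification failed (rank-deficient regressors)."""


class FitError(TwinPlatError, RuntimeError):
    """Impedance regression failed (degenerate regressors)."""


class UndefinedRatioError(TwinPlatError, ZeroDivisionError):
    """Symmetry ratio undefined (zero dominant stiffness)."""


class EmptyAcceptError(TwinPlatError, RuntimeError):
    """Trial screening rejected every trial; carries per-trial reasons."""

    def __init__(self, message: str, reasons=None):
        super().__init__(message)
        self.reasons = reasons or {}


class GenerationError(TwinPlatError, RuntimeError):
    """Synthetic-data generation failed (e.g. admittance divergence)."""


class MissingInputError(TwinPlatError, FileNotFoundError):
    """A dataset directory or required file is absent."""
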