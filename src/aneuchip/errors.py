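"""Exception hierarchy.

Exit-code mapping used by the CLI: validation/usage problems -> 2,
numerical failures -> 3.
"""


class AneuchipError(Exception):
    """Base class for all package errors."""


class UsageError(AneuchipError):
    """A function was called with arguments that violate its contract."""


class ResolutionError(UsageError):
    """Grid spacing too coarse to resolve the requested geometry."""


class GeometryError(AneuchipError):
    """A generated or processed mask violates a geometric invariant
    (e.g. the fluid region is disconnected)."""


class MeshFormatError(AneuchipError):
    """A surface mesh is unsuitable for voxelization (not watertight)."""


class ConfigError(UsageError):
    """Pipeline configuration failed validation."""


class NumericalError(AneuchipError):
    """Base class for solver failures."""


class InstabilityError(NumericalError):
    """Time integration produced NaN/Inf or exceeded the CFL bound."""

    def __init__(self, message: str, step: int | None = None, dt: float | None = None):
        super().__init__(message)
        self.step = step
        self.dt = dt


class ConvergenceError(NumericalError):
    """An iteration failed to reach its tolerance; carries the residual
    history so callers can inspect the convergence curve."""

    def __init__(self, message: str, residual_history=None):
        super().__init__(message)
        self.residual_history = residual_history
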