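"""Exception hierarchy shared across the package.

CLI exit-code contract: ValidationError -> 2, NumericalError -> 3,
IOFailure -> 4.
"""


class EVBKitError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(EVBKitError):
    """Invalid parameters, configuration, or domain violations."""

    exit_code = 2


class ShapeError(ValidationError):
    """Coordinate / particle count mismatch."""


class UnitError(ValidationError):
    """Incompatible units supplied to an arithmetic operation."""


class NumericalError(EVBKitError):
    """Numerical failure during simulation or estimation."""

    exit_code = 3


class InvalidConfigurationError(NumericalError):
    """Non-finite coordinates or energies."""


class IntegrationInstabilityError(NumericalError):
    """Energy divergence during dynamics; carries window and step context."""

    def __init__(self, message, lam=None, step=None):
        super().__init__(message)
        self.lam = lam
        self.step = step


class CoverageError(NumericalError):
    """Adjacent windows do not overlap on the gap coordinate."""


class NoBarrierError(NumericalError):
    """Profile has no interior maximum between two minima."""


class InfeasibleTargetError(NumericalError):
    """Calibration target cannot be bracketed (barrier above h_ij=0 value)."""


class IOFailure(EVBKitError):
    """File input/output failure, with path context."""

    exit_code = 4
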