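"""Exception hierarchy for the corset package."""


class CorsetError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(CorsetError, ValueError):
    """A scalar parameter is outside its allowed range."""


class InvalidShapeError(CorsetError, ValueError):
    """An axisymmetric profile violates its structural invariants."""


class DegenerateShapeError(InvalidShapeError):
    """The profile touches the symmetry axis at an interior node."""


class ModelValidityError(CorsetError, ValueError):
    """The small-curvature regime |J|·d < 1 is violated.

    The parallel-surface area relations only hold when the membrane
    separation is small compared to the local radii of curvature.
    """


class BranchError(CorsetError, ValueError):
    """Requested area difference lies on the oblate branch (not modelled)."""


class SolverError(CorsetError, RuntimeError):
    """Constrained minimization failed to converge.

    Carries the last iterate as ``solution`` for diagnosis.
    """

    def __init__(self, message, solution=None):
        super().__init__(message)
        self.solution = solution


class UnreachableTargetError(CorsetError, ValueError):
    """Target area difference unreachable within a trial shape family."""


class InvalidTraceError(CorsetError, ValueError):
    """A mitochondrion tracing violates the trace schema invariants."""


class CapacityError(CorsetError, ValueError):
    """Requested cristae cannot be placed at a realistic spacing."""


class DegenerateDataError(CorsetError, ValueError):
    """A statistic is undefined on the given data (e.g. zero variance)."""


class SchemaError(CorsetError, ValueError):
    """A trace file does not conform to the documented schema."""


class ConfigError(CorsetError, ValueError):
    """A pipeline configuration is malformed."""
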