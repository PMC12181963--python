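"""Exception hierarchy shared by all ifpmap modules."""


class IfpmapError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(IfpmapError):
    """An input table is missing a required column or field."""


class ParseError(IfpmapError):
    """A cell in an input table could not be parsed."""


class EmptyInputError(IfpmapError):
    """An operation received no usable data."""


class PartitionMismatchError(IfpmapError):
    """Two objects that must share a partition do not."""


class DomainError(IfpmapError):
    """A point lies outside the map's half-open domain."""


class InvalidMapError(IfpmapError):
    """A piecewise-linear map violates its structural invariants."""


class InvalidMatrixError(IfpmapError):
    """A transition matrix is not row-stochastic within tolerance."""


class ConvergenceError(IfpmapError):
    """An iterative solver failed to converge.

    Attributes
    ----------
    residual : float or None
        Final residual when the iteration stopped.
    """

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class GapError(IfpmapError):
    """A density time series has non-consecutive day indices."""


class ValidationError(IfpmapError):
    """A configuration value or argument is invalid."""


class EmptyGateError(IfpmapError):
    """A sorting gate captured no events from the parental population."""


class BoundaryError(IfpmapError):
    """Boundary handling failed to bring a value back into the domain."""


class DivergenceError(IfpmapError):
    """A quantity diverges (e.g. log-derivative on a zero-slope branch)."""
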