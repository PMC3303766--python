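"""Exception hierarchy shared across the package."""


class SnakeError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(SnakeError, ValueError):
    """Malformed or out-of-contract input (non-finite coordinates, bad shapes, ...)."""


class StencilWidthError(InvalidInputError):
    """Fewer nodes than the pentadiagonal stencil requires (N < 5)."""


class StabilityError(SnakeError):
    """Evolution requested with a time step violating the von Neumann criterion."""


class DivergenceError(SnakeError):
    """The explicit iteration produced non-finite or runaway iterates."""

    def __init__(self, message: str, iteration: int | None = None):
        super().__init__(message)
        self.iteration = iteration


class NonConstantCoefficientError(SnakeError):
    """Scalar ELP reduction requested in constant-coefficient form, but the
    computed coefficients vary with position."""


class DegenerateSurfaceError(SnakeError):
    """A surface cannot be assembled (fewer than two slices)."""
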