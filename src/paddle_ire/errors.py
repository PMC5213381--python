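"""Typed exceptions used throughout the package.

The CLI maps these to exit codes: validation/input problems exit 2,
numerical problems exit 3.
"""


class PaddleIREError(Exception):
    """Base class for all package errors."""


class DomainError(PaddleIREError, ValueError):
    """A physically meaningless argument (e.g. non-positive geometry)."""


class InputError(PaddleIREError, ValueError):
    """A structurally invalid input (empty grid, negative current, ...)."""


class SchemaError(InputError):
    """A CSV record that does not match the documented schema."""

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        loc = []
        if row is not None:
            loc.append(f"row {row}")
        if column is not None:
            loc.append(f"column {column!r}")
        if loc:
            message = f"{message} ({', '.join(loc)})"
        super().__init__(message)
        self.row = row
        self.column = column


class ValidationError(InputError):
    """A parsed record that violates a domain invariant."""


class EstimationError(PaddleIREError):
    """A threshold estimate that cannot be formed from the given sites."""


class NumericalError(PaddleIREError):
    """A numerical procedure failed (non-convergence, singular system)."""


class PrecisionError(NumericalError):
    """A quadrature/tabulation grid too short or coarse for the requested
    accuracy; the message carries the diagnostic."""


class DegenerateDesignError(NumericalError):
    """A statistical design with zero error variance."""
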