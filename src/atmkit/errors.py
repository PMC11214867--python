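"""Exception hierarchy.

All package-specific failures derive from :class:`AtmkitError` so callers
(and the CLI) can catch one base class and turn it into a clean exit.
"""


class AtmkitError(Exception):
    """Base class for all atmkit errors."""


class InvalidParameterError(AtmkitError, ValueError):
    """A physical or numerical parameter is out of its valid domain."""


class InvalidInputError(AtmkitError, ValueError):
    """Malformed or empty user input (arrays, lists, networks)."""


class SingularGeometryError(AtmkitError):
    """Coincident particles in a pair interaction make the energy singular."""


class ClassificationError(AtmkitError):
    """A potential term cannot be assigned to a unique ligand group."""


class InvalidScheduleError(AtmkitError):
    """A lambda schedule does not satisfy the two-leg ATM contract."""


class IntegrationFailureError(AtmkitError):
    """Dynamics produced a non-finite energy or gradient."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


class IncompleteSamplingError(AtmkitError):
    """A lambda window finished with zero recorded samples."""


class ConvergenceError(AtmkitError):
    """An iterative estimator failed to reach its tolerance."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class UndefinedCorrelationError(AtmkitError):
    """Rank correlation is undefined (e.g. an all-constant input)."""


class ParseError(AtmkitError, ValueError):
    """A file failed validation; carries the offending row/column."""

    def __init__(self, message: str, row: int | None = None,
                 column: str | None = None):
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
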