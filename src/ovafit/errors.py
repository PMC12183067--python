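"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: :class:`DataError` -> 2,
:class:`ConvergenceError` -> 3.
"""


class OvafitError(Exception):
    """Base class for all package-specific errors."""


class DomainError(OvafitError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class DataError(OvafitError, ValueError):
    """Input data are malformed, empty, or insufficient for the requested fit."""


class InvalidSurfaceError(DomainError):
    """A gamma surface violates mean > mode > 0 at some age."""


class ConvergenceError(OvafitError, RuntimeError):
    """The optimizer failed to converge.

    Carries the best fit found so far in :attr:`best_fit` when available.
    """

    def __init__(self, message: str, best_fit=None):
        super().__init__(message)
        self.best_fit = best_fit


class RankDeficiencyError(OvafitError, RuntimeError):
    """The Jacobian or design matrix is rank-deficient at the optimum."""


class SeparationError(OvafitError, RuntimeError):
    """Logistic-regression outcomes are completely separated by the design."""
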