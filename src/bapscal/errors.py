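"""Exception hierarchy.

All toolkit errors derive from :class:`BapsCalError` so callers can catch
one type at the pipeline boundary; the subclasses distinguish unphysical
inputs from infeasible protocols and degenerate statistics.
"""


class BapsCalError(Exception):
    """Base class for all toolkit errors."""


class DomainError(BapsCalError, ValueError):
    """Input outside the physical domain (non-positive T, dP >= P, ...)."""


class InfeasibleProtocolError(BapsCalError):
    """A gas-exchange protocol would remove more gas than a pool holds."""


class InsufficientDataError(BapsCalError):
    """Too few observations to compute the requested statistic."""


class SingularDesignError(BapsCalError):
    """Regression design matrix is singular (no signal variance)."""


class FitFailureError(BapsCalError):
    """Iterative fit did not converge; carries optimizer diagnostics."""


class UndefinedStatisticError(BapsCalError):
    """Statistic undefined for this input (e.g. all-zero residuals)."""


class InconsistentBudgetError(BapsCalError):
    """Stated measurement-error variance exceeds the observed residual variance."""
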