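"""Exception hierarchy for locpois."""


class LocPoisError(Exception):
    """Base class for all locpois errors."""


class ConfigurationError(LocPoisError):
    """Invalid configuration: unknown kernel family, bad column selection, bad config file."""


class DataValidationError(LocPoisError):
    """Input data violates the count-dataset contract (non-integer counts, missing values...)."""


class DegenerateNeighborhoodError(LocPoisError):
    """All kernel weights vanish (or are numerically negligible) around an evaluation point."""


class InitializationError(LocPoisError):
    """The OLS initializer cannot be computed (rank-deficient raw design)."""


class FitError(LocPoisError):
    """Newton-Raphson could not produce a usable fit (singular Hessian, divergence)."""


class SelectionError(LocPoisError):
    """Bandwidth selection failed (all grid points invalid, empty grid)."""


class ScenarioError(LocPoisError):
    """A simulation scenario is infeasible (e.g. implied Poisson mean above the cap)."""


class OutOfWindowWarning(UserWarning):
    """A local model was evaluated outside its validity window (x0 +/- h)."""
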