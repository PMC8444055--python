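"""Exception hierarchy for the adherence-gap pipeline."""


class AdherenceGapError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AdherenceGapError):
    """A configuration value is missing, malformed or out of range."""


class ContractViolationError(AdherenceGapError):
    """An operation precondition was violated (e.g. unsorted input)."""


class ValidationError(AdherenceGapError):
    """Input data fail a plausibility or range check."""


class AnalysisError(AdherenceGapError):
    """A model cannot be fitted on the data provided (e.g. no
    within-set contrast, no informative sets)."""


class ConvergenceError(AnalysisError):
    """The conditional-likelihood optimiser failed to converge,
    typically because of separation.  ``covariate`` names the term
    whose coefficient diverged."""

    def __init__(self, message: str, covariate: str | None = None):
        super().__init__(message)
        self.covariate = covariate
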