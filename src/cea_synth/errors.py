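"""Exception hierarchy shared across the package."""


class CEASynthError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CEASynthError):
    """Input data violates a structural invariant."""


class ParseError(CEASynthError):
    """A tabular input file could not be parsed."""


class ImputationError(CEASynthError):
    """Missing values cannot be imputed (no observed donors)."""


class ConfigError(CEASynthError):
    """Run configuration is invalid or unsupported."""


class DegenerateSampleError(CEASynthError):
    """All importance weights are zero; the posterior sample is unusable."""


class PriorDataConflictError(CEASynthError):
    """Rejection sampling exceeded its attempt budget.

    Raised when the external evidence and the trial data are in such
    conflict that the acceptance rate is too low to reach the requested
    number of accepted draws within ``max_attempts``.
    """

    def __init__(self, message: str, attempts: int, accepted: int):
        super().__init__(message)
        self.attempts = attempts
        self.accepted = accepted
        self.acceptance_rate = accepted / attempts if attempts else 0.0
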