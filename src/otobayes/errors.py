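"""Exception hierarchy shared across the package."""


class OtobayesError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(OtobayesError, ValueError):
    """Malformed or inconsistent input (bad schema, length mismatch, bad config)."""


class DomainError(OtobayesError, ValueError):
    """Input outside the mathematical domain of an operation."""


class ConvergenceError(OtobayesError, RuntimeError):
    """An MCMC fit failed its convergence thresholds in strict mode."""
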