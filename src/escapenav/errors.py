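"""Exception taxonomy shared across the package."""


class EscapeNavError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EscapeNavError):
    """Invalid configuration or missing fixture."""


class ValidationError(EscapeNavError):
    """Input data violates a documented invariant."""


class ContractViolationError(EscapeNavError):
    """A precondition of an operation was violated by the caller."""


class InvalidSessionError(ValidationError):
    """A tracking session cannot be registered to the grid world."""


class PosteriorDomainError(ValidationError):
    """The printed Beta-posterior update produced a non-positive shape."""
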