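"""Exception hierarchy shared by all pipeline stages."""


class ECoGError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(ECoGError):
    """A file could be opened but its contents violate the expected format."""


class ValidationError(ECoGError):
    """Input data violates a documented precondition or invariant."""


class ConfigurationError(ECoGError):
    """A configuration value is unknown, missing, or inconsistent."""


class DegenerateInputError(ECoGError):
    """Input is degenerate for the requested computation (e.g. zero variance)."""


class TrainingDivergenceError(ECoGError):
    """Optimization produced a non-finite loss; reports the offending epoch."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite training loss at epoch {epoch}")
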