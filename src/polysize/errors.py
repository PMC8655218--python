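"""Exception types shared across the package."""


class PolysizeError(Exception):
    """Base class for all package-specific errors."""


class ParseError(PolysizeError, ValueError):
    """A repeat-unit SMILES could not be parsed or validated."""


class FeaturizationError(PolysizeError, ValueError):
    """An atom could not be featurized under the active feature spec."""


class ShapeError(PolysizeError, ValueError):
    """Array dimensions do not chain; message names both shapes."""


class ValidationError(PolysizeError, ValueError):
    """Invalid argument or configuration value."""


class ConfigError(PolysizeError, ValueError):
    """Inconsistent configuration (generator or model)."""


class NotFittedError(PolysizeError, RuntimeError):
    """A prediction was requested from an unfitted model."""


class TrainingError(PolysizeError, RuntimeError):
    """Training diverged; carries the epoch index in the message."""

    def __init__(self, message: str, epoch: int | None = None):
        super().__init__(message)
        self.epoch = epoch
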