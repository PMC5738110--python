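"""Exception hierarchy.

Validation errors (bad inputs or configuration, detectable before any
computation) are distinct from runtime errors so the CLI can map them to
different exit codes.
"""


class OmicsFSError(Exception):
    """Base class for all package errors."""


class ValidationError(OmicsFSError):
    """Invalid input data or configuration."""


class DimensionMismatchError(ValidationError):
    pass


class DuplicateIdError(ValidationError):
    pass


class ClassSizeError(ValidationError):
    """A class level has too few samples for the requested operation."""


class ConstantOutcomeError(ValidationError):
    """Regression outcome is constant (or non-finite)."""


class ConfigError(ValidationError):
    """Invalid workflow configuration (unknown step, forbidden order, ...)."""


class NoCompleteFeaturesError(OmicsFSError):
    """Every feature has at least one missing value."""


class EmptyFilterResultError(OmicsFSError):
    """A filter dropped every feature."""

    def __init__(self, message: str, max_score: float | None = None):
        super().__init__(message)
        self.max_score = max_score


class ZeroVarianceError(OmicsFSError):
    """Zero-variance column where a correlation is required."""


class MultiClassCorrelationError(ValidationError):
    """Correlation scoring asked for a >2-class outcome."""


class FoldConstructionError(ValidationError):
    """Cross-validation folds cannot be built (class smaller than folds)."""


class MissingFeatureError(OmicsFSError):
    """Prediction input lacks features the fitted model requires."""

    def __init__(self, missing_ids):
        self.missing_ids = list(missing_ids)
        super().__init__(
            "prediction input is missing required feature ids: "
            + ", ".join(self.missing_ids)
        )


class StepError(OmicsFSError):
    """Wraps an error raised inside a named workflow step."""

    def __init__(self, step_name: str, original: Exception):
        self.step_name = step_name
        self.original = original
        super().__init__(f"step '{step_name}' failed: {original}")
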