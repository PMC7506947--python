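"""Exception hierarchy for the throwspeed package."""


class ThrowspeedError(Exception):
    """Base class for all package errors."""


class ConfigError(ThrowspeedError, ValueError):
    """Invalid configuration value; carries the offending field name."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class ParameterError(ThrowspeedError, ValueError):
    """Invalid operation parameter (e.g. cutoff at or above Nyquist)."""


class GenerationError(ThrowspeedError, ValueError):
    """Synthetic signal cannot be generated from the given truth."""


class SizeError(ThrowspeedError, ValueError):
    """Input too small or empty for the requested operation."""


class DataError(ThrowspeedError, ValueError):
    """Malformed or incomplete data rows (unknown level, missing column)."""


class DomainError(ThrowspeedError, ValueError):
    """Value outside the mathematical domain of an operation."""


class NoReleaseError(ThrowspeedError, RuntimeError):
    """No frame satisfied the ball-release criterion."""


class FittingError(ThrowspeedError, ValueError):
    """Model cannot be fitted (rank deficiency, too few rows)."""


class FoldError(ThrowspeedError, RuntimeError):
    """A cross-validation fold could not be refitted."""

    def __init__(self, fold: int, message: str):
        self.fold = fold
        super().__init__(f"fold {fold}: {message}")


class MetricError(ThrowspeedError, ValueError):
    """A performance metric is undefined for the given inputs."""


class PipelineError(ThrowspeedError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
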