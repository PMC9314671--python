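"""Exception hierarchy.

Every error raised by the package derives from :class:`CryosdmError`, so
pipeline code can distinguish analysis failures from programming errors.
"""


class CryosdmError(Exception):
    """Base class for all package errors."""


class GridConflictError(CryosdmError):
    """Layers that should share a grid have incompatible dimensions/transforms."""


class EmptyDomainError(CryosdmError):
    """A crop or mask removed every cell."""


class ConfigurationError(CryosdmError):
    """Invalid configuration value (unknown CRS, bad resolution, ...)."""


class DataError(CryosdmError):
    """Input data violates a documented contract (e.g. unknown substrate code)."""


class SchemaError(CryosdmError):
    """Tabular input is missing mandatory columns or names do not match."""


class EmptyPresenceError(CryosdmError):
    """No presence record survives masking/deduplication; species unmodellable."""


class EmptyBackgroundError(CryosdmError):
    """Target-group background is empty."""


class ExtractionError(CryosdmError):
    """A requested cell is invalid in a covariate layer."""


class DegenerateCovariateError(CryosdmError):
    """A covariate column is constant and cannot enter a VIF regression."""


class ConvergenceError(CryosdmError):
    """Optimiser failed to reach the gradient tolerance within its budget."""

    def __init__(self, message: str, grad_norm: float):
        super().__init__(message)
        self.grad_norm = grad_norm


class FoldError(CryosdmError):
    """Cross-validation folds cannot be built as requested."""


class DegenerateBlockError(FoldError):
    """All presences fall in a single spatial block."""


class EvaluationError(CryosdmError):
    """An evaluation statistic is undefined on the given inputs."""


class DegenerateThresholdError(EvaluationError):
    """All predictions identical; no threshold separates anything."""


class StackingError(CryosdmError):
    """Cannot stack an empty collection of binary maps."""


class SummaryError(CryosdmError):
    """Area summary requested without the required present-day projection."""


class UndefinedChangeError(CryosdmError):
    """Percent change against a zero present-day area."""


class SamplingError(CryosdmError):
    """Requested more presence samples than available cells."""


class ParameterError(CryosdmError):
    """Virtual-species parameters yield an empty true range."""


class SeedError(CryosdmError):
    """Random generation repeatedly produced a degenerate field."""


class ValidationError(CryosdmError):
    """Run configuration failed validation."""
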