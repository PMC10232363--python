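"""Exception hierarchy shared across the pipeline stages."""


class NutriscreenError(Exception):
    """Base class for all package errors."""


class ConfigError(NutriscreenError):
    """Invalid synthetic-data or pipeline configuration."""


class ParameterError(NutriscreenError):
    """Invalid analysis parameter (window, abundance fraction, ...)."""


class DataError(NutriscreenError):
    """Input table violates a structural contract (missing controls, no shared samples, ...)."""


class UndefinedCorrelationError(DataError):
    """Spearman correlation undefined: a rank vector has zero variance."""


class DegenerateSplitError(DataError):
    """All scores identical; a high/low split is undefined."""


class DegenerateDesignError(DataError):
    """Standard-curve design is rank deficient (fewer than 3 distinct levels)."""


class UnquantifiableError(DataError):
    """Standard curve has zero slope; responses cannot be inverted."""


class UndefinedMIDError(DataError):
    """All-zero isotopologue areas; distribution undefined."""


class StageError(NutriscreenError):
    """A pipeline stage failed; downstream stages were not run."""
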