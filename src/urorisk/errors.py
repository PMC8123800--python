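"""Exception hierarchy shared across the package."""


class UroriskError(Exception):
    """Base class for all package errors."""


class ConfigurationError(UroriskError):
    """Invalid generator or pipeline configuration."""


class ValidationError(UroriskError):
    """Cohort records fail validation (missing or inconsistent fields)."""


class NormalisationError(UroriskError):
    """Positive-control normalisation cannot be computed for a sample."""


class SchemaError(UroriskError):
    """Requested variables or columns are absent from the table."""


class DegenerateInputError(UroriskError):
    """Input is structurally valid but degenerate (e.g. single-class label)."""


class MetricError(UroriskError):
    """A metric is undefined for the given inputs (e.g. single-class AUC)."""


class ResamplingError(UroriskError):
    """Stratified resampling cannot be performed (e.g. empty stratum)."""
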