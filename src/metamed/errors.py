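"""Exception hierarchy shared across the pipeline stages.

Every stage raises a subclass of :class:`MetamedError`; the CLI maps these
to distinct exit codes so shell callers can distinguish bad configuration
from bad input data from estimation failures.
"""


class MetamedError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MetamedError):
    """Invalid simulation or run configuration; message names the field."""


class InputError(MetamedError):
    """Input table violates a stage precondition."""


class ModelError(MetamedError):
    """Regression design is degenerate (rank deficiency, collinearity)."""


class ImputationError(MetamedError):
    """Below-LOD imputation impossible (no measured values in a plate)."""


class NormalizationError(MetamedError):
    """Plate normalization factor undefined (zero reference median)."""


class TransformError(MetamedError):
    """Log/scale transform hit a nonpositive value or zero-variance column."""


class InstrumentError(MetamedError):
    """No genetic instruments survive selection."""


class EstimatorError(MetamedError):
    """MR estimator preconditions violated (e.g. zero exposure beta)."""


class SummaryError(MetamedError):
    """Cohort summarizer hit an empty stratum."""


class DependencyError(MetamedError):
    """A pipeline stage is enabled but its upstream output is missing."""
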