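"""Exception hierarchy for the kpbiofilm pipeline."""


class KPBiofilmError(Exception):
    """Base class for all package errors."""


class ConfigurationError(KPBiofilmError):
    """A generator or pipeline configuration field is invalid."""


class ParameterError(KPBiofilmError):
    """An operation parameter is out of its valid range or unattainable."""


class DataError(KPBiofilmError):
    """Input data violate the operation's preconditions."""


class DomainError(KPBiofilmError):
    """A physical quantity is outside the model's domain (e.g. |phase| >= 90 deg)."""


class EstimationError(KPBiofilmError):
    """A nonlinear-dynamics estimator could not produce a result."""


class FitError(KPBiofilmError):
    """A distribution fit is degenerate (e.g. zero variance)."""


class NormalizationError(KPBiofilmError):
    """Min-max normalization is undefined (constant signal)."""
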