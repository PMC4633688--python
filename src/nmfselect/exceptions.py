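"""Exception hierarchy shared across the package."""


class NMFSelectError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NMFSelectError):
    """A file does not follow the expected on-disk layout."""


class ValidationError(NMFSelectError):
    """Input data violates a structural invariant."""


class EmptyDatasetError(ValidationError):
    """An operation would leave a dataset with no features or samples."""


class LabelingError(NMFSelectError):
    """A substage code has no entry in the substage-to-stage map."""


class StratificationError(NMFSelectError):
    """A requested stratum or class is empty."""


class QuotaError(NMFSelectError):
    """A (class, covariate) cell has fewer samples than the requested quota."""


class DegenerateInputError(NMFSelectError):
    """Input is degenerate for the requested computation (e.g. all-zero matrix)."""


class NumericalError(NMFSelectError):
    """A numerical computation failed (singular system, non-finite objective)."""


class ConfigError(NMFSelectError):
    """Invalid configuration value."""
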