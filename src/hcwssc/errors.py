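"""Exception hierarchy shared across the package."""


class HcwsscError(Exception):
    """Base class for package errors."""


class DimensionMismatchError(HcwsscError, ValueError):
    """Two spectra (or a cube and its wavelength axis) disagree in band count."""


class DegenerateInputError(HcwsscError, ValueError):
    """Input is outside a measure's admissible domain (all-zero, constant, ...)."""


class SelectionError(HcwsscError, RuntimeError):
    """Fewer than two candidate measures survive the feature-selection filter."""


class ConfigurationError(HcwsscError, ValueError):
    """Inconsistent run configuration (e.g. more clusters than distinct pixels)."""


class GenerationError(HcwsscError, RuntimeError):
    """Synthetic-data constraints could not be satisfied within the retry budget."""


class EvaluationError(HcwsscError, ValueError):
    """Evaluation is impossible (empty overlap, empty confusion matrix)."""


class UndefinedKappaError(EvaluationError):
    """Chance agreement equals 1, leaving the kappa coefficient undefined."""


class FormatError(HcwsscError, ValueError):
    """A file does not conform to the expected on-disk format."""
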