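"""Exception hierarchy shared across the pipeline."""


class FirspecError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(FirspecError, ValueError):
    """A configuration object violates its invariants."""


class EnviParseError(FirspecError, ValueError):
    """An ENVI header or binary file could not be interpreted."""


class EnviSizeMismatchError(EnviParseError):
    """Header dimensions do not match the binary payload size."""


class UnknownInterleaveError(EnviParseError):
    """Interleave tag is not one of the supported layouts (bsq, bil)."""


class MissingWavelengthError(EnviParseError):
    """Header lacks a wavelength list, or its length disagrees with `bands`."""


class ReferenceDegeneracyError(FirspecError, ValueError):
    """White and dark reference coincide at some pixel/band, so (I-D)/(W-D) is undefined."""


class EmptyROIError(FirspecError, ValueError):
    """The canopy mask selects no pixels; a mean spectrum cannot be formed."""


class DegenerateSpectrumError(FirspecError, ValueError):
    """A per-spectrum transform (SNV, MSC) hit a zero-variance or zero-gain spectrum."""


class BandMismatchError(FirspecError, ValueError):
    """Prediction-time band set differs from the bands a model was trained on."""


class StratificationError(FirspecError, ValueError):
    """A group is too small (or absent) for a stratified split."""


class UndefinedMetricError(FirspecError, ValueError):
    """Metric denominator is zero (e.g. R^2 with a constant reference vector)."""


class TrainingDivergenceError(FirspecError, RuntimeError):
    """Model training produced a non-finite loss or non-finite parameters."""
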