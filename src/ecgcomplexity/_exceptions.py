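"""Exception hierarchy shared across the package."""


class EcgError(Exception):
    """Base class for all package errors."""


class ParameterError(EcgError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(EcgError, ValueError):
    """An input file does not conform to the expected CSV dialect."""


class UnsupportedOperationError(EcgError):
    """A requested operation is outside the supported envelope (e.g. upsampling)."""


class InsufficientDataError(EcgError):
    """Not enough samples / beats / points to compute the quantity."""


class AnnotationError(EcgError):
    """Fiducial annotation failed for an entire strip."""


class AnnotationCollisionError(AnnotationError):
    """Two fiducial markers mapped onto the same sample index."""


class UndefinedMetricError(EcgError):
    """The requested statistic is undefined for this input (e.g. zero-variance data)."""


class FitError(EcgError):
    """Polynomial heart-rate correction could not be fitted."""


class LabellingError(EcgError):
    """A subject lacks a valid case/control label."""
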