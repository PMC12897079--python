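"""Exception hierarchy shared across the pipeline stages."""


class LesionRoiError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LesionRoiError, ValueError):
    """Invalid configuration value (shape, ratio, negative margin, ...)."""


class DegenerateInputError(LesionRoiError, ValueError):
    """Structurally valid input that the operation cannot act on.

    Examples: an all-zero lesion mask, an empty slice-probability list,
    single-class labels passed to an ROC computation.
    """


class AlignmentError(LesionRoiError, ValueError):
    """Paired arrays (image/mask, score vectors) whose shapes disagree."""


class LeakageError(LesionRoiError, RuntimeError):
    """A patient appears on both sides of a train/validation split.

    Raised as a hard failure: patient-level partitioning is the central
    methodological guarantee of the pipeline.
    """
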