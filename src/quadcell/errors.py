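"""Exception hierarchy shared across the package."""


class QuadcellError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(QuadcellError, ValueError):
    """Invalid parameter or data container contents."""


class ModalityError(QuadcellError, TypeError):
    """Operation applied to a trace/frame of the wrong modality."""


class AlignmentError(QuadcellError):
    """Recording cannot be folded onto a common stimulus-relative axis."""


class EstimationError(QuadcellError):
    """Requested estimate is not identifiable from the supplied data."""


class SchemaError(QuadcellError):
    """On-disk layout missing or written by an incompatible schema version."""


class CoverageError(QuadcellError, ValueError):
    """Scan measurements do not cover the electrode grid."""
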