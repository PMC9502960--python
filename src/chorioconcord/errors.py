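"""Exception taxonomy for the concordance pipeline.

Every failure mode the pipeline can surface has a dedicated class so that
callers (and the CLI) can distinguish bad inputs from bad configuration
without string matching.
"""


class ChorioconcordError(Exception):
    """Base class for all package errors."""


class RoiFormatError(ChorioconcordError):
    """Byte stream is not a valid ImageJ ROI record."""


class UnsupportedRoiTypeError(RoiFormatError):
    """ROI record is valid but of a subtype the pipeline does not model."""


class InvalidRoiError(ChorioconcordError):
    """A RegionOfInterest violates its invariants (no rings, short ring...)."""


class ShapeMismatchError(ChorioconcordError):
    """Raster dimensions disagree with the declared image frame."""


class InsufficientLandmarksError(ChorioconcordError):
    """Fewer than three landmark pairs were supplied."""


class DegenerateLandmarksError(ChorioconcordError):
    """Moving landmarks are (numerically) collinear; the affine is not identifiable."""


class SingularTransformError(ChorioconcordError):
    """Affine transform is not invertible where inversion is required."""


class UndefinedOverlapError(ChorioconcordError):
    """Jaccard index requested for a pair of regions with empty union."""


class MissingAnnotationError(ChorioconcordError):
    """A required lesion label is absent from an annotation set."""


class EmptyInputError(ChorioconcordError):
    """A summary or test was requested on an empty collection."""


class DegenerateInputError(ChorioconcordError):
    """Statistical test input carries no usable information (e.g. all-zero diffs)."""


class MissingBaselineError(ChorioconcordError):
    """An eye has follow-up measurements but no baseline (timepoint 0) visit."""


class ConfigurationError(ChorioconcordError):
    """Run configuration or generator parameters are inconsistent."""
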