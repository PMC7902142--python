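"""Exception hierarchy for the gait-anomaly pipeline.

Every error a stage can raise maps to one class here so callers can catch
`GaitAnomalyError` at the pipeline boundary and still discriminate causes.
"""


class GaitAnomalyError(Exception):
    """Base class for all package errors."""


class InsufficientFramesError(GaitAnomalyError):
    """Fewer raw frames than key location points."""


class BlankFrameError(GaitAnomalyError):
    """A frame with no foreground pixels where foreground is required."""


class InvalidKernelError(GaitAnomalyError):
    """Morphological kernel size is even or non-positive."""


class ShapeMismatchError(GaitAnomalyError):
    """Frames or energy images with inconsistent dimensions."""


class DegenerateImageError(GaitAnomalyError):
    """An image with no gray-level separation (e.g. constant) where a
    discriminating threshold is required."""


class EmptyMaskError(GaitAnomalyError):
    """Energy mask with zero on-pixels; overlap features are undefined."""


class InconsistentLabelsError(GaitAnomalyError):
    """Pre-labeled subsets overlap."""


class ConstraintViolationError(GaitAnomalyError):
    """COP-K-means could not find any constraint-satisfying assignment."""


class UnknownSubjectError(GaitAnomalyError):
    """A labeled subject index has no feature vector."""


class AmbiguousMappingError(GaitAnomalyError):
    """Labeled-normal subjects split evenly between clusters; the
    cluster-to-class mapping is undefined."""


class EmptyInputError(GaitAnomalyError):
    """An operation received an empty list where at least one element is
    required (no frames, no GEIs, empty cohort, empty initiation...)."""
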