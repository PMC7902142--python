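"""Deviation features: energy-mask segmentation and overlap statistics.

The F-GEI is thresholded into a binary energy mask E marking the
high-density region where involved subjects most frequently appear. Each
subject's overlap vector holds, per frame, the fraction of E covered by
that frame's silhouette; its mean and standard deviation form the 2-D
feature vector used for classification. Summarizing over frames makes the
feature insensitive to gait phase, so subjects sampled at different points
of their stride remain comparable.
"""

from __future__ import annotations

import numpy as np
from skimage.filters import threshold_otsu

from .errors import DegenerateImageError, EmptyInputError, EmptyMaskError, ShapeMismatchError
from .types import FGEI, EnergyMask, FeatureVector, GaitSequence, OverlapVector

__all__ = [
    "select_threshold",
    "segment_energy_mask",
    "overlap_vector",
    "feature_vector",
]


def select_threshold(
    fgei: FGEI, method: str = "otsu", fixed_value: float | None = None
) -> float:
    """Choose the gray-level threshold T for energy-mask segmentation.

    ``method="fixed"`` passes ``fixed_value`` through; ``method="otsu"``
    maximizes between-class variance over the strictly positive pixels
    (zero background would otherwise dominate the histogram).
    """
    if method == "fixed":
        if fixed_value is None:
            raise ValueError("fixed_value required when method='fixed'")
        if not 0.0 < fixed_value <= 255.0:
            raise ValueError(f"threshold must be in (0, 255], got {fixed_value}")
        return float(fixed_value)
    if method != "otsu":
        raise ValueError(f"unknown threshold method {method!r}")
    positive = fgei.pixels[fgei.pixels > 0]
    if positive.size == 0 or np.ptp(positive) == 0:
        raise DegenerateImageError("degenerate image: no gray-level separation for Otsu")
    return float(threshold_otsu(positive))


def segment_energy_mask(fgei: FGEI, T: float) -> EnergyMask:
    """Binary mask E(x,y) = 255 where F(x,y) >= T, else 0."""
    if T <= 0:
        raise ValueError(f"threshold must be positive, got {T}")
    mask = np.where(fgei.pixels >= T, np.uint8(255), np.uint8(0))
    return EnergyMask(pixels=mask, threshold_used=float(T))


def overlap_vector(sequence: GaitSequence, mask: EnergyMask) -> OverlapVector:
    """Per-frame fraction of the energy mask's on-pixels covered by the
    subject's silhouette: o_j = |B_j ∩ E| / |E|."""
    n_on = mask.n_on
    if n_on == 0:
        raise EmptyMaskError("empty energy mask")
    mask_on = mask.pixels == 255
    values = np.empty(sequence.n_frames, dtype=np.float64)
    for j, frame in enumerate(sequence.frames):
        if frame.shape != mask.pixels.shape:
            raise ShapeMismatchError(
                f"shape mismatch: frame {frame.shape} vs mask {mask.pixels.shape}"
            )
        values[j] = np.count_nonzero((frame == 255) & mask_on) / n_on
    return OverlapVector(values=values, subject_id=sequence.subject_id)


def feature_vector(o: OverlapVector, *, ddof: int = 0) -> FeatureVector:
    """(mean, standard deviation) of the overlap vector.

    The default is the population standard deviation (divisor N): the
    overlap vector is a fixed N-element description of one subject, not a
    sample from a larger population. Pass ``ddof=1`` for the sample
    convention in sensitivity checks.
    """
    if o.values.size == 0:
        raise EmptyInputError("no elements in overlap vector")
    if o.values.size <= ddof:
        raise ValueError(f"need more than {ddof} elements for ddof={ddof}")
    return FeatureVector(
        mean=float(o.values.mean()),
        std=float(o.values.std(ddof=ddof)),
        subject_id=o.subject_id,
    )
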