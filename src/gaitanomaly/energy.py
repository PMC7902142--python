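"""Gait Energy Images and the population-level Full GEI.

A GEI is the pixel-wise mean of one subject's N aligned binary silhouette
frames; brighter pixels are positions the body occupies in more frames.
The Full GEI (F-GEI) is the pixel-wise mean of the GEIs of all subjects
involved so far — the population's energy distribution — and supports an
exact incremental update so the online detector never has to revisit past
subjects' frames:

    F_M = (G_M + (M - 1) * F_{M-1}) / M

where M counts accumulated GEIs. All arithmetic is double precision; the
F-GEI is never quantized to 8-bit internally (repeated incremental
averaging in 8-bit would drift).
"""

from __future__ import annotations

import numpy as np

from .errors import EmptyInputError, ShapeMismatchError
from .types import FGEI, GEI, GaitSequence

__all__ = ["compute_gei", "compute_fgei_batch", "update_fgei"]


def compute_gei(sequence: GaitSequence | list[np.ndarray], subject_id: str = "") -> GEI:
    """Pixel-wise mean of the subject's binary frames: G(x,y) = (1/N) sum_t B_t(x,y)."""
    if isinstance(sequence, GaitSequence):
        frames, sid = sequence.frames, sequence.subject_id
    else:
        frames, sid = list(sequence), subject_id
    if not frames:
        raise EmptyInputError("no frames")
    shapes = {np.asarray(f).shape for f in frames}
    if len(shapes) > 1:
        raise ShapeMismatchError(f"shape mismatch among frames: {shapes}")
    stack = np.stack([np.asarray(f, dtype=np.float64) for f in frames])
    return GEI(pixels=stack.mean(axis=0), subject_id=sid, n_frames=len(frames))


def compute_fgei_batch(geis: list[GEI]) -> FGEI:
    """Pixel-wise mean of M GEIs (batch form)."""
    if not geis:
        raise EmptyInputError("no GEIs")
    shapes = {g.pixels.shape for g in geis}
    if len(shapes) > 1:
        raise ShapeMismatchError(f"shape mismatch among GEIs: {shapes}")
    stack = np.stack([g.pixels.astype(np.float64) for g in geis])
    return FGEI(pixels=stack.mean(axis=0), m_count=len(geis))


def update_fgei(fgei: FGEI | None, new_gei: GEI) -> FGEI:
    """Fold one more GEI into the running F-GEI.

    With ``fgei=None`` this initializes the accumulator at M=1. Otherwise
    applies the incremental mean update with M = fgei.m_count + 1.
    """
    if fgei is None:
        return FGEI(pixels=new_gei.pixels.astype(np.float64).copy(), m_count=1)
    if fgei.pixels.shape != new_gei.pixels.shape:
        raise ShapeMismatchError(
            f"shape mismatch: F-GEI {fgei.pixels.shape} vs GEI {new_gei.pixels.shape}"
        )
    m = fgei.m_count + 1
    pixels = (new_gei.pixels.astype(np.float64) + (m - 1) * fgei.pixels) / m
    return FGEI(pixels=pixels, m_count=m)
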