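"""Silhouette preprocessing: frame selection, denoising, body extraction,
size normalization and centroid alignment.

Turns a raw ordered silhouette sequence into exactly N clean frames on a
common canvas, ready for energy-image computation. Frames are selected at
virtual key location points spaced along the walking path, so the same
number of frames is retained for every subject regardless of gait speed;
the retained frames need not cover complete gait cycles.
"""

from __future__ import annotations

import logging

import numpy as np
from skimage.measure import label as cc_label
from scipy import ndimage
from skimage.transform import resize

from .errors import BlankFrameError, InsufficientFramesError, InvalidKernelError
from .types import GaitSequence, KeyPointLayout, RawFrame, as_binary

logger = logging.getLogger(__name__)

__all__ = [
    "select_frames",
    "denoise",
    "extract_body",
    "normalize_align",
    "preprocess_sequence",
    "clean_sequence",
]


def select_frames(raw_frames: list[RawFrame], layout: KeyPointLayout) -> list[RawFrame]:
    """Pick one frame per key location point: the frame whose horizontal
    foreground centroid is nearest that key point's x position.

    Selection is greedy in key-point order over the frames not yet used;
    a frame serves at most one key point. Ties (two frames equidistant
    from a key point) resolve to the earlier frame index.
    """
    if len(raw_frames) < layout.n_points:
        raise InsufficientFramesError(
            f"insufficient frames: {len(raw_frames)} < {layout.n_points} key points"
        )
    centroids = []
    for f in raw_frames:
        if not f.has_foreground:
            raise BlankFrameError(f"blank frame at index {f.frame_index}")
        centroids.append(f.centroid_x)

    remaining = list(range(len(raw_frames)))
    selected: list[RawFrame] = []
    for x in layout.x_positions:
        # min over (distance, original frame index) -> earlier frame on ties
        best = min(remaining, key=lambda i: (abs(centroids[i] - x), raw_frames[i].frame_index))
        selected.append(raw_frames[best])
        remaining.remove(best)
    return selected


def denoise(frame: np.ndarray, kernel_size: int = 3) -> np.ndarray:
    """Morphological closing (dilation then erosion) with a square
    structuring element of side ``kernel_size``; fills small holes and
    gaps left by the silhouette extraction."""
    if kernel_size < 1 or kernel_size % 2 == 0:
        raise InvalidKernelError(f"invalid kernel: size {kernel_size} must be odd and >= 1")
    arr = as_binary(frame)
    if kernel_size == 1:
        return arr.copy()
    # pad so the dilation never hits the array border: this realizes the
    # closing on an infinite zero background (no edge erosion artifacts)
    pad = kernel_size // 2
    se = np.ones((kernel_size, kernel_size), dtype=bool)
    padded = np.pad(arr > 0, kernel_size, constant_values=False)
    closed = ndimage.binary_erosion(ndimage.binary_dilation(padded, se), se)
    closed = closed[kernel_size:-kernel_size, kernel_size:-kernel_size]
    return closed.astype(np.uint8) * 255


def extract_body(frame: np.ndarray, bottom_cut_fraction: float = 0.05) -> np.ndarray:
    """Keep the largest 8-connected foreground component and cut a fraction
    of its bounding-box height from the bottom (removes floor artifacts
    attached to the feet)."""
    if not 0.0 <= bottom_cut_fraction < 1.0:
        raise ValueError(f"bottom_cut_fraction must be in [0,1), got {bottom_cut_fraction}")
    arr = as_binary(frame)
    if not np.any(arr):
        raise BlankFrameError("blank frame: no foreground to extract")
    labels = cc_label(arr > 0, connectivity=2)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    keep = int(np.argmax(sizes))
    body = np.where(labels == keep, np.uint8(255), np.uint8(0))
    if bottom_cut_fraction > 0.0:
        rows = np.flatnonzero(body.any(axis=1))
        top, bottom = rows[0], rows[-1]
        bbox_h = bottom - top + 1
        n_cut = int(round(bottom_cut_fraction * bbox_h))
        if n_cut > 0:
            body[bottom - n_cut + 1 : bottom + 1, :] = 0
    if not np.any(body):
        raise BlankFrameError("blank frame: bottom cut removed all foreground")
    return body


def _normalize_one(frame: np.ndarray, target_w: int, target_h: int) -> np.ndarray:
    arr = as_binary(frame)
    ys, xs = np.nonzero(arr)
    if xs.size == 0:
        raise BlankFrameError("blank frame: cannot normalize empty silhouette")
    top, bottom = ys.min(), ys.max()
    left, right = xs.min(), xs.max()
    crop = arr[top : bottom + 1, left : right + 1]
    bbox_h, bbox_w = crop.shape
    scale = target_h / bbox_h
    new_w = max(1, int(round(bbox_w * scale)))
    # bilinear resize of the binary crop, then re-binarize at 50% gray
    scaled = resize(
        crop.astype(float), (target_h, new_w), order=1, anti_aliasing=False, mode="constant"
    )
    sil = (scaled > 127.5).astype(np.uint8) * 255
    if not np.any(sil):
        # thin silhouettes can vanish under strict 50% re-binarization
        sil = (scaled >= 127.5).astype(np.uint8) * 255
        if not np.any(sil):
            raise BlankFrameError("blank frame: silhouette vanished during scaling")

    canvas = np.zeros((target_h, target_w), dtype=np.uint8)
    cx = float(np.nonzero(sil)[1].mean())
    # place the silhouette so its centroid column sits at the canvas center
    offset = int(round((target_w - 1) / 2.0 - cx))
    src_l = max(0, -offset)
    src_r = min(sil.shape[1], target_w - offset)
    if src_l > 0 or src_r < sil.shape[1]:
        logger.warning(
            "canvas overflow: silhouette width %d exceeds canvas %d after centering; clipping",
            sil.shape[1],
            target_w,
        )
    if src_r > src_l:
        canvas[:, src_l + offset : src_r + offset] = sil[:, src_l:src_r]
    return canvas


def normalize_align(
    frames: list[np.ndarray], target_w: int = 88, target_h: int = 128
) -> list[np.ndarray]:
    """Scale each silhouette so its foreground bounding-box height equals
    ``target_h`` (aspect preserved, re-binarized at 50% gray), then place
    it on a ``target_w`` x ``target_h`` canvas with the foreground centroid
    at the horizontal center. Silhouettes wider than the canvas are
    clipped with a warning."""
    return [_normalize_one(f, target_w, target_h) for f in frames]


def preprocess_sequence(
    raw_frames: list[RawFrame],
    layout: KeyPointLayout,
    *,
    subject_id: str = "",
    true_label: str | None = None,
    kernel_size: int = 3,
    bottom_cut_fraction: float = 0.05,
    target_w: int = 88,
    target_h: int = 128,
) -> GaitSequence:
    """Full preprocessing chain for one subject: select N frames at the key
    points, denoise, extract the body, normalize and align."""
    selected = select_frames(raw_frames, layout)
    cleaned = [
        extract_body(denoise(f.pixels, kernel_size), bottom_cut_fraction) for f in selected
    ]
    aligned = normalize_align(cleaned, target_w, target_h)
    return GaitSequence(subject_id=subject_id, frames=aligned, true_label=true_label)


def clean_sequence(
    sequence: GaitSequence,
    *,
    kernel_size: int = 3,
    bottom_cut_fraction: float = 0.05,
    target_w: int = 88,
    target_h: int = 128,
) -> GaitSequence:
    """Denoise, extract the body and normalize an already frame-selected
    sequence (e.g. a synthetic one) onto the canonical canvas."""
    cleaned = [
        extract_body(denoise(f, kernel_size), bottom_cut_fraction) for f in sequence.frames
    ]
    aligned = normalize_align(cleaned, target_w, target_h)
    return GaitSequence(
        subject_id=sequence.subject_id, frames=aligned, true_label=sequence.true_label
    )
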