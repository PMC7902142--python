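"""Core data containers shared across the pipeline stages.

Conventions
-----------
* Silhouette frames are 2-D ``numpy`` arrays of shape ``(H, W)`` with dtype
  ``uint8`` and values restricted to ``{0, 255}`` (foreground = 255).
* Coordinates are 0-based; ``(x, y)`` means ``(column, row)`` with the origin
  at the top-left corner.
* Energy images (GEI / F-GEI) are float64 arrays in ``[0, 255]`` of the same
  canvas shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NORMAL = "normal"
ABNORMAL = "abnormal"

BINARY_VALUES = frozenset({0, 255})


def as_binary(frame: np.ndarray) -> np.ndarray:
    """Validate and return a {0, 255} uint8 frame.

    Raises ``ValueError`` on pixel values outside {0, 255}.
    """
    arr = np.asarray(frame)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D frame, got shape {arr.shape}")
    vals = np.unique(arr)
    if not set(int(v) for v in vals) <= BINARY_VALUES:
        raise ValueError(f"frame is not binary {{0,255}}: values {vals[:10]}")
    return arr.astype(np.uint8, copy=False)


def foreground_centroid_x(frame: np.ndarray) -> float:
    """Horizontal centroid (column, fractional) of the foreground pixels."""
    ys, xs = np.nonzero(frame)
    if xs.size == 0:
        raise ValueError("centroid undefined: frame has no foreground")
    return float(xs.mean())


@dataclass
class RawFrame:
    """A captured binary silhouette frame before selection/cleanup."""

    pixels: np.ndarray
    frame_index: int

    def __post_init__(self) -> None:
        self.pixels = as_binary(self.pixels)

    @property
    def centroid_x(self) -> float:
        return foreground_centroid_x(self.pixels)

    @property
    def has_foreground(self) -> bool:
        return bool(np.any(self.pixels))


@dataclass(frozen=True)
class KeyPointLayout:
    """Evenly spaced virtual key location points along the walking path.

    One frame is selected per key point (the frame whose horizontal
    foreground centroid is nearest), so ``n_points`` equals the number of
    frames N retained per subject.
    """

    x_positions: tuple[float, ...]

    def __post_init__(self) -> None:
        xs = tuple(float(x) for x in self.x_positions)
        if len(xs) < 1:
            raise ValueError("need at least one key point")
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise ValueError("key-point x positions must be strictly increasing")
        object.__setattr__(self, "x_positions", xs)

    @property
    def n_points(self) -> int:
        return len(self.x_positions)

    @classmethod
    def evenly_spaced(cls, n_points: int, x_min: float, x_max: float) -> "KeyPointLayout":
        return cls(tuple(np.linspace(x_min, x_max, n_points)))


@dataclass
class GaitSequence:
    """One subject's ordered silhouette frames plus identity and optional label."""

    subject_id: str
    frames: list[np.ndarray]
    true_label: str | None = None

    def __post_init__(self) -> None:
        if self.true_label not in (None, NORMAL, ABNORMAL):
            raise ValueError(f"unknown label {self.true_label!r}")
        self.frames = [as_binary(f) for f in self.frames]
        shapes = {f.shape for f in self.frames}
        if len(shapes) > 1:
            raise ValueError(f"frames have mixed dimensions: {shapes}")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape


@dataclass
class GEI:
    """Gait Energy Image: pixel-wise mean of one subject's binary frames."""

    pixels: np.ndarray
    subject_id: str = ""
    n_frames: int = 0


@dataclass
class FGEI:
    """Full GEI: running pixel-wise mean of all involved subjects' GEIs.

    ``m_count`` is the number of GEIs accumulated so far.
    """

    pixels: np.ndarray
    m_count: int


@dataclass
class EnergyMask:
    """Binary segmentation of the F-GEI at threshold T (high-density region)."""

    pixels: np.ndarray
    threshold_used: float

    @property
    def n_on(self) -> int:
        return int(np.count_nonzero(self.pixels))


@dataclass
class OverlapVector:
    """Per-frame fractions of the energy mask covered by a subject's frames."""

    values: np.ndarray
    subject_id: str = ""


@dataclass
class FeatureVector:
    """(mean, std) of the overlap vector — the 2-D clustering space."""

    mean: float
    std: float
    subject_id: str = ""

    def as_array(self) -> np.ndarray:
        return np.array([self.mean, self.std], dtype=float)


@dataclass
class LabeledSets:
    """Disjoint pre-labeled subject-index subsets, keyed by class label.

    ``subsets`` maps a class label ("normal" / "abnormal") to a set of
    subject indices. lambda (the number of distinct pre-labeled classes)
    is 1 when only one class is represented and 2 otherwise.
    """

    subsets: dict[str, set[int]]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for label, idxs in self.subsets.items():
            if label not in (NORMAL, ABNORMAL):
                raise ValueError(f"unknown class label {label!r}")
            if seen & idxs:
                from .errors import InconsistentLabelsError

                raise InconsistentLabelsError(
                    f"inconsistent labels: indices {sorted(seen & idxs)} in two subsets"
                )
            seen |= idxs
        if not seen:
            raise ValueError("labeled sets are empty")

    @property
    def n_classes(self) -> int:
        return sum(1 for s in self.subsets.values() if s)

    @property
    def all_indices(self) -> set[int]:
        return set().union(*self.subsets.values())


@dataclass(frozen=True)
class ConstraintSet:
    """Must-link / cannot-link pairs over subject indices (unordered pairs)."""

    must_links: frozenset[tuple[int, int]]
    cannot_links: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        for name, pairs in (("must", self.must_links), ("cannot", self.cannot_links)):
            for a, b in pairs:
                if a == b:
                    raise ValueError(f"self-pair ({a},{a}) in {name}-links")
        if self.must_links & self.cannot_links:
            raise ValueError("a pair is both must-linked and cannot-linked")

    @staticmethod
    def _norm(pairs) -> frozenset[tuple[int, int]]:
        return frozenset(tuple(sorted(p)) for p in pairs)

    @classmethod
    def build(cls, must_links=(), cannot_links=()) -> "ConstraintSet":
        return cls(cls._norm(must_links), cls._norm(cannot_links))

    @classmethod
    def empty(cls) -> "ConstraintSet":
        return cls(frozenset(), frozenset())


@dataclass
class ClusterBounds:
    """Per-class, per-dimension (min, max) boxes over labeled feature values."""

    boxes: dict[str, tuple[np.ndarray, np.ndarray]]  # label -> (mins, maxs)

    def contains(self, point: np.ndarray, label: str) -> bool:
        mins, maxs = self.boxes[label]
        return bool(np.all(point >= mins) and np.all(point <= maxs))


@dataclass
class ClusterAssignment:
    """Result of a (constrained) K-means run."""

    labels: np.ndarray  # per-point cluster index in 0..K-1
    centers: np.ndarray  # (K, d)
    converged: bool
    n_iterations: int
    inertia: float
    n_distance_evals: int = 0


@dataclass
class DetectionRecord:
    """Per-subject outcome of one online detection step."""

    subject_id: str
    subject_index: int
    predicted: str
    clamped: bool
    m_at_detection: int
    true_label: str | None = None


@dataclass
class EvaluationReport:
    """CCR / ACCR summary over a finished detection run."""

    ccr: float
    accr: float | None
    n_abnormal: int
    records: list[DetectionRecord] = field(default_factory=list)
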