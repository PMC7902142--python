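"""The online detection flow: initiation over the first L subjects, then
per-subject detection, plus CCR/ACCR evaluation.

Two stages:

1. **Initiation** — the first L subjects arrive with labels from visual
   inspection. Their GEIs seed the F-GEI and their indices form the
   labeled sets that drive clamping and constraints. No predictions are
   emitted for them.
2. **Detection** — each later subject's GEI is folded into the F-GEI, the
   energy mask is recomputed from the updated F-GEI, overlap features are
   (re)computed, and boundary-clamped constrained clustering produces the
   subject's normal/abnormal call at the moment it passes. Emitted records
   are final: later clustering runs never revise an earlier subject's
   recorded prediction.

By default the features of *all* involved subjects are recomputed against
the current energy mask before each clustering run, so every vector in one
run refers to the same mask (``frozen_features=True`` instead keeps each
subject's features as computed at its own arrival).

Because the F-GEI accumulates over arrivals, the presentation order of the
subjects genuinely affects results; runs are deterministic for a fixed
order and seed, and repeated trials reseed as ``seed + trial``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from . import clustering, energy, features
from .errors import EmptyInputError, GaitAnomalyError, ShapeMismatchError
from .types import (
    ABNORMAL,
    NORMAL,
    FGEI,
    DetectionRecord,
    EvaluationReport,
    FeatureVector,
    GaitSequence,
    LabeledSets,
)

__all__ = [
    "RunConfig",
    "PipelineState",
    "run_initiation",
    "detect_next",
    "run_stream",
    "ccr",
    "accr",
    "evaluate",
]


@dataclass(frozen=True)
class RunConfig:
    """Knobs of one online run.

    ``n_initiation`` is L, the number of pre-labeled subjects consumed
    before detection starts; ``threshold_method`` picks how the energy
    mask's gray threshold is chosen from the current F-GEI.
    """

    n_initiation: int = 4
    threshold_method: str = "otsu"
    fixed_threshold: float | None = None
    frozen_features: bool = False
    seed: int = 0
    max_iter: int = 100

    def __post_init__(self) -> None:
        if self.n_initiation < 1:
            raise ValueError("n_initiation (L) must be >= 1")


@dataclass
class PipelineState:
    """Everything the online detector carries between subjects."""

    config: RunConfig
    fgei: FGEI | None = None
    sequences: list[GaitSequence] = field(default_factory=list)
    feature_cache: list[FeatureVector] = field(default_factory=list)
    labeled: LabeledSets | None = None
    records: list[DetectionRecord] = field(default_factory=list)
    clustering_calls: int = 0
    clamp_events: int = 0

    @property
    def n_involved(self) -> int:
        return len(self.sequences)


def run_initiation(sequences: list[GaitSequence], config: RunConfig) -> PipelineState:
    """Consume the first L labeled subjects: fold their GEIs into the F-GEI
    and build the labeled sets. Detection is disabled during this stage,
    so no records are produced."""
    if not sequences:
        raise EmptyInputError("empty initiation: need at least one labeled subject")
    if len(sequences) != config.n_initiation:
        raise ValueError(
            f"expected L={config.n_initiation} initiation subjects, got {len(sequences)}"
        )
    shapes = {s.shape for s in sequences}
    if len(shapes) > 1:
        raise ShapeMismatchError(f"shape mismatch among initiation subjects: {shapes}")
    state = PipelineState(config=config)
    subsets: dict[str, set[int]] = {NORMAL: set(), ABNORMAL: set()}
    for idx, seq in enumerate(sequences):
        if seq.true_label not in (NORMAL, ABNORMAL):
            raise GaitAnomalyError(
                f"initiation subject {seq.subject_id!r} lacks a visual-inspection label"
            )
        gei = energy.compute_gei(seq)
        state.fgei = energy.update_fgei(state.fgei, gei)
        state.sequences.append(seq)
        state.feature_cache.append(FeatureVector(np.nan, np.nan, seq.subject_id))
        subsets[seq.true_label].add(idx)
    state.labeled = LabeledSets(subsets={k: v for k, v in subsets.items() if v})
    return state


def _refresh_features(state: PipelineState, mask) -> list[FeatureVector]:
    """Features of all involved subjects against the current mask; under
    ``frozen_features`` earlier subjects keep their cached vectors."""
    out: list[FeatureVector] = []
    for idx, seq in enumerate(state.sequences):
        cached = state.feature_cache[idx]
        if state.config.frozen_features and np.isfinite(cached.mean):
            out.append(cached)
            continue
        o = features.overlap_vector(seq, mask)
        out.append(features.feature_vector(o))
    state.feature_cache = out
    return out


def detect_next(state: PipelineState, sequence: GaitSequence) -> DetectionRecord:
    """Process one arriving subject and emit its detection record.

    Updates the F-GEI incrementally, recomputes the energy mask and the
    feature vectors, then classifies via boundary-clamped constrained
    clustering seeded deterministically from the run seed and the
    subject's arrival index.
    """
    if state.labeled is None or state.fgei is None:
        raise GaitAnomalyError("initiation incomplete: call run_initiation first")
    if sequence.shape != state.fgei.pixels.shape:
        raise ShapeMismatchError(
            f"subject {sequence.subject_id!r}: frames {sequence.shape} vs "
            f"canvas {state.fgei.pixels.shape}"
        )
    new_index = state.n_involved
    gei = energy.compute_gei(sequence)
    state.fgei = energy.update_fgei(state.fgei, gei)
    state.sequences.append(sequence)
    state.feature_cache.append(FeatureVector(np.nan, np.nan, sequence.subject_id))

    T = features.select_threshold(
        state.fgei, state.config.threshold_method, state.config.fixed_threshold
    )
    mask = features.segment_energy_mask(state.fgei, T)
    points = _refresh_features(state, mask)

    step_seed = (state.config.seed + 1009 * (new_index + 1)) % (2**31)
    result = clustering.bc_cop_kmeans(
        points,
        state.labeled,
        new_index,
        seed=step_seed,
        max_iter=state.config.max_iter,
    )
    if result.clamped:
        state.clamp_events += 1
    else:
        state.clustering_calls += 1
    record = DetectionRecord(
        subject_id=sequence.subject_id,
        subject_index=new_index,
        predicted=result.new_label,
        clamped=result.clamped,
        m_at_detection=state.fgei.m_count,
        true_label=sequence.true_label,
    )
    state.records.append(record)
    return record


def run_stream(
    sequences: Iterable[GaitSequence], config: RunConfig
) -> PipelineState:
    """Run the full two-stage flow over an ordered subject stream."""
    sequences = list(sequences)
    L = config.n_initiation
    if len(sequences) <= L:
        raise ValueError(f"need more than L={L} subjects, got {len(sequences)}")
    state = run_initiation(sequences[:L], config)
    for seq in sequences[L:]:
        detect_next(state, seq)
    return state


def ccr(records: list[DetectionRecord]) -> float:
    """Correct classification rate over the post-initiation subjects:
    the fraction of emitted predictions matching the known labels."""
    if not records:
        raise EmptyInputError("no detection records")
    missing = [r.subject_id for r in records if r.true_label is None]
    if missing:
        raise GaitAnomalyError(f"unlabeled ground truth for subjects {missing}")
    hits = sum(1 for r in records if r.predicted == r.true_label)
    return hits / len(records)


def accr(records: list[DetectionRecord]) -> float:
    """Anomaly correct classification rate: the fraction of truly abnormal
    post-initiation subjects that were detected as abnormal."""
    abnormal = [r for r in records if r.true_label == ABNORMAL]
    if not abnormal:
        raise EmptyInputError("no abnormal subjects: ACCR undefined")
    hits = sum(1 for r in abnormal if r.predicted == ABNORMAL)
    return hits / len(abnormal)


def evaluate(state: PipelineState) -> EvaluationReport:
    """CCR/ACCR report for a finished run; ACCR is None when the stream
    contained no truly abnormal subject after initiation."""
    records = state.records
    n_abn = sum(1 for r in records if r.true_label == ABNORMAL)
    return EvaluationReport(
        ccr=ccr(records),
        accr=accr(records) if n_abn else None,
        n_abnormal=n_abn,
        records=list(records),
    )
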