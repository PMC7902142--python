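"""Semisupervised classification: constraints, clamping, COP-K-means.

A handful of labeled subjects supply must-link/cannot-link constraints and
per-class bounding boxes. A new subject inside exactly one class's box is
clamped to that class with no clustering at all; otherwise constrained
K-means partitions everyone.
"""

from gaitanomaly.clustering import (
    bc_cop_kmeans,
    boundary_clamp,
    compute_bounds,
    generate_constraints,
)
from gaitanomaly.types import ABNORMAL, NORMAL, FeatureVector, LabeledSets

pts = [
    FeatureVector(0.95, 0.02, "n1"),
    FeatureVector(0.92, 0.03, "n2"),
    FeatureVector(0.96, 0.025, "n3"),
    FeatureVector(0.65, 0.01, "a1"),
]
labeled = LabeledSets({NORMAL: {0, 1, 2}, ABNORMAL: {3}})
cs = generate_constraints(labeled)
print(f"constraints from labels: {len(cs.must_links)} must-link, "
      f"{len(cs.cannot_links)} cannot-link")

bounds = compute_bounds(pts, labeled)
inside = FeatureVector(0.94, 0.025, "new-in")
outside = FeatureVector(0.68, 0.015, "new-out")
print(f"{inside.subject_id}: clamp -> {boundary_clamp(inside, bounds)}")
print(f"{outside.subject_id}: clamp -> {boundary_clamp(outside, bounds)}")

for new in (inside, outside):
    res = bc_cop_kmeans(pts + [new], labeled, new_index=4, seed=0)
    print(f"{new.subject_id}: label={res.new_label}, clamped={res.clamped}, "
          f"distance evaluations={res.n_distance_evals}")
print(
    "The in-box subject is classified with zero distance computations; the "
    "out-of-box one triggers a full constrained clustering run."
)
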