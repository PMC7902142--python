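# Methods

This note records the model, the defaults and the design choices behind
`gaitanomaly`, and what the synthetic experiments do and do not show.

## Problem setting and model

Subjects pass a detection point one at a time; for each, the system
receives an ordered sequence of binary side-view silhouettes and must emit
a normal/abnormal call immediately. The first *L* subjects ("initiation
stage") arrive with labels from visual inspection and receive no calls;
everything afterwards is detected online. The method assumes silhouettes
are already segmented from the background (as a depth camera provides),
that exactly two gait classes exist, and that abnormal gait distorts the
silhouette's geometry relative to the population — it does not model
timing, since the features deliberately discard gait phase.

The pipeline is: frame selection at key locations → morphological cleanup
→ normalization/alignment → per-subject GEI → running population F-GEI →
energy-mask segmentation → per-subject overlap features → boundary-clamped
constrained K-means. Each stage's contract is in its module docstring; the
parameters that matter are below.

## Parameters and defaults

| parameter | default | meaning / rationale |
|---|---|---|
| `N` (frames per subject) | 16 | one frame per key location point; equal for every subject so GEIs are commensurate |
| `L` (`RunConfig.n_initiation`) | 4 | labeled subjects consumed before detection starts; 6 and 8 are natural sensitivity settings |
| canvas (`target_w x target_h`) | 88 x 128 px | the conventional gait-template size; silhouettes are scaled to full canvas height, aspect preserved |
| closing kernel | 3 x 3 square, one dilation + one erosion | smallest symmetric element that fills 1-px holes without fattening limbs; closing is computed on a zero background (padded), so edge-touching silhouettes are not eroded |
| `bottom_cut_fraction` | 0.05 | removes floor pixels attached to the feet, as a fraction of the body bounding-box height |
| connectivity for the largest component | 8 | diagonal pixel contact keeps thin limbs attached |
| re-binarization threshold after scaling | 127.5 (50% gray) | unbiased rounding of the interpolated binary image |
| threshold method for the energy mask | Otsu over strictly positive F-GEI pixels | the zero background would otherwise dominate the histogram; a `fixed` value is available |
| overlap-std convention | population (divisor *N*) | the overlap vector is a complete *N*-element description of one subject, not a sample |
| K-means init | K distinct points drawn uniformly without replacement, seeded | simple, and restarts cover initialization sensitivity |
| restarts `R` | 10 | see "constrained clustering" below |
| convergence | assignments unchanged, or `max_iter` = 100 | |

Frame-selection ties (two frames equidistant from a key point) go to the
earlier frame; a frame may serve only one key point, assigned greedily in
key-point order. Boundary-box membership is inclusive (min ≤ v ≤ max); a
point inside zero or ≥ 2 class boxes falls through to clustering.

## Feature recomputation policy

A subject's overlap features depend on the current energy mask, which
moves as the F-GEI accumulates. At each detection step the mask is
recomputed from the updated F-GEI and the features of *all* involved
subjects are recomputed against it before clustering, so every vector in
one clustering run refers to the same mask. The alternative — freezing
each subject's features as computed at its own arrival — is available as
`RunConfig(frozen_features=True)` for sensitivity checks. Recomputation
was chosen for internal consistency: mixing vectors measured against
different masks would make distances between them meaningless.

Emitted detection records are final. A later clustering run may internally
place an earlier subject differently, but the record written when that
subject passed is never revised, matching the online reading of the task.
Labeled sets never grow: predictions are not promoted into supervision, to
avoid self-training drift.

## Constrained clustering

The classical COP-K-means pass assigns points one by one to the nearest
center that violates no constraint against points already placed, and
fails when some point has no feasible cluster. That greedy pass is
order-sensitive: it can dead-end on perfectly satisfiable instances (a
point cannot-linked to two points that earlier choices scattered across
both clusters) and it settles in order-dependent local optima. This
package instead makes the assignment step *exactly*
constraint-respecting, exploiting the binary-classification structure:

- Must-link connected components move as single units (in the detection
  application they are exactly the labeled-class cliques).
- With K = 2, the cannot-link graph over those units forces a 2-coloring
  within each connected constraint block, so each block has exactly two
  admissible orientations; the assignment step takes the cheaper one by
  summed squared distance to the centers (ties keep color-0 on cluster 0).

Unsatisfiable constraints — a cannot-link inside a must-link group, or a
non-2-colorable cannot-link graph — raise `ConstraintViolationError`
immediately; a satisfiable instance can never dead-end, so the failure
mode is decided by the constraints alone, not by visitation order. Up to
R = 10 seeded center re-initializations cover the usual K-means
initialization sensitivity; a run that oscillates instead of stabilizing
(Lloyd 2-cycles exist on tied geometry) is returned only as a last
resort, flagged `converged=False`.

An emptied cluster is reseeded at the point farthest from its assigned
center, dragging that point's whole must-link component (a cluster can
only empty when no cannot-link exists, so this is always admissible).
Distances are Euclidean on the raw 2-D feature space; both coordinates
are overlap proportions on a comparable scale, so no standardization is
applied.

With only one labeled class (λ = 1) and K = 2, clustering must split a
possibly homogeneous cohort; the split is accepted and the cluster holding
the labeled normals is read as "normal". Boundary clamping is precisely
the mitigation for this forced split: a new subject inside the labeled
box never reaches the clustering step.

## Synthetic cohorts: what they emulate and what they don't

The generator renders a parametric binary walker — rectangular torso, disc
head, two legs whose horizontal spread follows a sinusoidal phase — with
per-subject jitter in body proportions and starting phase, and optional
salt-and-pepper noise and interior holes. Rasterization is integer-only,
so noise-free cohorts are bit-reproducible across platforms.

Abnormality is geometric, not temporal: the default mode is a postural
**lean** (shear, 0.12·(effect−1) px/row), because the overlap feature
responds to displacement of silhouette mass relative to the population's
high-energy region. The `asymmetry` and `reduced_stride` modes perturb
only the legs, whose extreme positions fall below the energy-mask
threshold; they produce weak feature separation and are retained exactly
because they demonstrate that boundary of the method's sensitivity. At
`effect_size = 1` every mode reduces to the normal parameters, giving a
null cohort. The default cohort is 62 subjects with 12 abnormal and
N = 16, a realistic screening-scale composition.

Passing tests on these cohorts show that the pipeline recovers a known
geometric deviation under controlled conditions; they do not show
robustness to clothing variation, carried objects, imperfect background
subtraction, viewpoint change, or anomalies expressed mainly in timing —
real silhouette data differ in all of these ways.

## Numerical choices and degenerate inputs

F-GEI arithmetic is double precision throughout and the stored state is
never quantized to 8 bits (repeated incremental averaging in uint8 would
drift); incremental and batch forms agree to ~1e-15 relative error. An
all-zero or constant F-GEI makes Otsu undefined and raises
`DegenerateImageError`; an empty energy mask raises `EmptyMaskError`
rather than dividing by zero. Blank frames are rejected wherever a
centroid or bounding box is required. A silhouette wider than the canvas
after height normalization is clipped with a warning. Detection-step
seeds are derived as `seed + 1009·(index+1)`, keeping replays of the same
stream byte-identical while decoupling steps.

## Experiment sizes

The bundled experiments run the default 62-subject cohort over 10 random
presentation orders for each of 5 cohort seeds (50 online runs, 2 900
decisions) for the separable case, and 2 orders × 5 seeds for the null
case; clustering correctness is checked on 200 random constrained
instances (n ≤ 30) and optimality against exhaustive bipartition search on
50 instances (n ≤ 10, best of 20 seeds). These sizes give stable means
while keeping a full reproduction run around a minute on one CPU.

## Known limitations

- Two classes only (K = 2 is structural, not a parameter).
- The feature is blind to anomalies that preserve the silhouette's
  occupancy of the high-energy region (e.g. purely temporal limping).
- The F-GEI is order-sensitive early on: the first few subjects dominate
  the mask, so presentation order genuinely affects results (tests assert
  per-order determinism, never order invariance).
- Boundary clamping inherits the labeled sample's box: with very few
  labeled subjects the box is small and clamping rarely fires; with
  outlier labels it can clamp wrongly. The labeled subjects are trusted
  ground truth and never re-scored.
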