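"""Semisupervised binary classification by boundary-clamped constrained
K-means.

The classifier gets its supervision from a small set of pre-labeled
subjects. Two mechanisms exploit them:

* **Pairwise constraints** (COP-K-means): every within-class labeled pair
  becomes a must-link, every cross-class pair a cannot-link, and the
  K-means assignment step only ever produces constraint-satisfying
  partitions — must-link groups move as single units, and with K=2 the
  cannot-link graph fixes each constraint block's two admissible
  orientations, of which the cheaper is taken. Unsatisfiable constraints
  fail hard; satisfiable ones never dead-end.
* **Boundary clamping**: before any clustering, a new subject whose
  feature vector falls inside the per-dimension (min, max) box of exactly
  one labeled class is assigned that class directly and clustering is
  skipped. This both reuses the labeled samples a second way and avoids
  the failure mode where K=2 clustering is forced to split a cohort that
  is in fact all one class.

K is fixed at 2 here (normal vs abnormal); the code keeps K general where
it costs nothing.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .errors import (
    AmbiguousMappingError,
    ConstraintViolationError,
    UnknownSubjectError,
)
from .types import (
    ABNORMAL,
    NORMAL,
    ClusterAssignment,
    ClusterBounds,
    ConstraintSet,
    FeatureVector,
    LabeledSets,
)

logger = logging.getLogger(__name__)

__all__ = [
    "generate_constraints",
    "cop_kmeans",
    "compute_bounds",
    "boundary_clamp",
    "bc_cop_kmeans",
    "map_clusters",
    "BCResult",
]


def generate_constraints(labeled: LabeledSets) -> ConstraintSet:
    """Must-link every within-class labeled pair; cannot-link every
    cross-class pair."""
    must: set[tuple[int, int]] = set()
    cannot: set[tuple[int, int]] = set()
    groups = [sorted(s) for s in labeled.subsets.values() if s]
    for g in groups:
        must.update(itertools.combinations(g, 2))
    for ga, gb in itertools.combinations(groups, 2):
        cannot.update((min(a, b), max(a, b)) for a in ga for b in gb)
    return ConstraintSet.build(must, cannot)


def _as_matrix(points: list[FeatureVector] | np.ndarray) -> np.ndarray:
    if isinstance(points, np.ndarray):
        X = np.asarray(points, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return X
    return np.array([p.as_array() for p in points], dtype=float)


def _must_link_components(n: int, constraints: ConstraintSet) -> list[np.ndarray]:
    """Connected components of the must-link graph (singletons included)."""
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in constraints.must_links:
        parent[find(a)] = find(b)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return [np.array(g) for g in groups.values()]


def _constraint_blocks(
    n: int, K: int, constraints: ConstraintSet
) -> tuple[list[np.ndarray], list[np.ndarray], list[np.ndarray]]:
    """Decompose the constraint graph into independently assignable units.

    Must-link components are the atoms. Cannot-links connect atoms into
    blocks; within a block the 2-coloring of the cannot-link graph is
    forced (up to a swap), so with K=2 every block has exactly two
    admissible assignments. Returns (components, sides0, sides1): for each
    block, the point indices on each color side (free blocks have an empty
    side 1). Raises ``ConstraintViolationError`` when the constraints are
    unsatisfiable (a cannot-link inside a must-link component, or an
    odd cannot-cycle with K=2).
    """
    components = _must_link_components(n, constraints)
    comp_of = np.empty(n, dtype=int)
    for ci, members in enumerate(components):
        comp_of[members] = ci
    adj: dict[int, set[int]] = {ci: set() for ci in range(len(components))}
    for a, b in constraints.cannot_links:
        ca, cb = int(comp_of[a]), int(comp_of[b])
        if ca == cb:
            raise ConstraintViolationError(
                "constraint violation failure: cannot-link inside a must-link group"
            )
        adj[ca].add(cb)
        adj[cb].add(ca)
    if K != 2 and constraints.cannot_links:
        raise NotImplementedError("cannot-link constraints are supported for K=2 only")

    color = {}
    sides0, sides1 = [], []
    for start in range(len(components)):
        if start in color:
            continue
        color[start] = 0
        queue, block = [start], [start]
        while queue:
            u = queue.pop()
            for v in adj[u]:
                if v not in color:
                    color[v] = 1 - color[u]
                    queue.append(v)
                    block.append(v)
                elif color[v] == color[u]:
                    raise ConstraintViolationError(
                        "constraint violation failure: cannot-links are not 2-colorable"
                    )
        s0 = np.concatenate([components[c] for c in block if color[c] == 0])
        ones = [components[c] for c in block if color[c] == 1]
        s1 = np.concatenate(ones) if ones else np.array([], dtype=int)
        sides0.append(s0)
        sides1.append(s1)
    return components, sides0, sides1


def _cop_kmeans_once(
    X: np.ndarray,
    K: int,
    constraints: ConstraintSet,
    rng: np.random.Generator,
    max_iter: int,
    blocks: tuple[list[np.ndarray], list[np.ndarray], list[np.ndarray]],
) -> ClusterAssignment | None:
    n = X.shape[0]
    centers = X[rng.choice(n, size=K, replace=False)].copy()
    assign = np.full(n, -1, dtype=int)
    n_dist = 0
    components, sides0, sides1 = blocks
    comp_of = np.empty(n, dtype=int)
    for ci, members in enumerate(components):
        comp_of[members] = ci

    for it in range(1, max_iter + 1):
        new_assign = np.full(n, -1, dtype=int)
        for s0, s1 in zip(sides0, sides1):
            d0 = np.sum((X[s0][:, None, :] - centers[None, :, :]) ** 2, axis=(0, 2))
            n_dist += K * len(s0)
            if s1.size == 0:
                # unconstrained side: the whole unit takes its nearest center
                new_assign[s0] = int(np.argmin(d0))
                continue
            # a cannot-constrained block has two admissible orientations;
            # take the cheaper (ties keep side 0 on cluster 0)
            d1 = np.sum((X[s1][:, None, :] - centers[None, :, :]) ** 2, axis=(0, 2))
            n_dist += K * len(s1)
            if d0[0] + d1[1] <= d0[1] + d1[0]:
                new_assign[s0], new_assign[s1] = 0, 1
            else:
                new_assign[s0], new_assign[s1] = 1, 0
        # recompute centers; reseed an emptied center to the point farthest
        # from its currently assigned center
        for c in range(K):
            members = new_assign == c
            if members.any():
                centers[c] = X[members].mean(axis=0)
        for c in range(K):
            if not (new_assign == c).any():
                # reseed an emptied cluster at the point farthest from its
                # center, dragging that point's whole must-link component
                dists = np.sum((X - centers[new_assign]) ** 2, axis=1)
                n_dist += n
                far = int(np.argmax(dists))
                moved = components[comp_of[far]]
                centers[c] = X[far]
                new_assign[moved] = c
        if np.array_equal(new_assign, assign):
            inertia = float(np.sum((X - centers[assign]) ** 2))
            return ClusterAssignment(
                labels=assign,
                centers=centers,
                converged=True,
                n_iterations=it,
                inertia=inertia,
                n_distance_evals=n_dist,
            )
        assign = new_assign
    inertia = float(np.sum((X - centers[assign]) ** 2))
    return ClusterAssignment(
        labels=assign,
        centers=centers,
        converged=False,
        n_iterations=max_iter,
        inertia=inertia,
        n_distance_evals=n_dist,
    )


def cop_kmeans(
    points: list[FeatureVector] | np.ndarray,
    K: int,
    constraints: ConstraintSet | None = None,
    seed: int = 0,
    max_iter: int = 100,
    n_restarts: int = 10,
) -> ClusterAssignment:
    """Constrained K-means: K-means iteration whose assignment step is
    exactly constraint-respecting.

    Constraints are honored through their transitive structure: must-link
    components move as single units, and with K=2 the cannot-link graph
    over those units forces a 2-coloring within each connected block, so
    every block has exactly two admissible orientations and the assignment
    step simply takes the cheaper one (by summed squared distance to the
    centers). Unsatisfiable constraints — a cannot-link inside a must-link
    group, or cannot-links whose graph is not 2-colorable — raise
    ``ConstraintViolationError`` immediately; no satisfiable instance can
    dead-end. Up to ``n_restarts`` seeded center re-initializations cover
    the usual K-means initialization sensitivity; a run that oscillates
    instead of converging is kept only as a last-resort fallback.

    Distances are taken on the raw feature space — both coordinates are
    overlap proportions on a comparable scale, so no standardization.
    """
    X = _as_matrix(points)
    n = X.shape[0]
    if K > n:
        raise ValueError(f"K={K} exceeds number of points {n}")
    constraints = constraints or ConstraintSet.empty()
    blocks = _constraint_blocks(n, K, constraints)
    fallback: ClusterAssignment | None = None
    for attempt in range(n_restarts):
        rng = np.random.default_rng(seed + attempt)
        result = _cop_kmeans_once(X, K, constraints, rng, max_iter, blocks)
        if result is not None and result.converged:
            if attempt > 0:
                logger.info("cop_kmeans converged after %d restart(s)", attempt)
            return result
        if result is not None:  # completed but oscillating: keep the best
            if fallback is None or result.inertia < fallback.inertia:
                fallback = result
    logger.warning("cop_kmeans never converged in %d attempts", n_restarts)
    return fallback


def compute_bounds(
    points: list[FeatureVector], labeled: LabeledSets
) -> ClusterBounds:
    """Per labeled class, the per-dimension (min, max) box over that
    class's labeled members only. Unlabeled subjects never widen a box."""
    X = _as_matrix(points)
    boxes: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for label, idxs in labeled.subsets.items():
        if not idxs:
            continue
        bad = [i for i in idxs if i >= X.shape[0] or i < 0]
        if bad:
            raise UnknownSubjectError(f"unknown subject indices {bad}: no feature vector")
        sub = X[sorted(idxs)]
        boxes[label] = (sub.min(axis=0), sub.max(axis=0))
    return ClusterBounds(boxes=boxes)


def boundary_clamp(v: FeatureVector, bounds: ClusterBounds) -> str | None:
    """Assign ``v`` directly to a labeled class when it falls inside that
    class's box in every dimension and inside no other class's box.
    Membership is inclusive (min <= v <= max). Inside zero boxes or two or
    more boxes -> ``None`` (ambiguous; defer to clustering)."""
    p = v.as_array()
    hits = [label for label in bounds.boxes if bounds.contains(p, label)]
    return hits[0] if len(hits) == 1 else None


def map_clusters(
    assignment: ClusterAssignment, labeled: LabeledSets
) -> dict[int, str]:
    """Name the clusters: the cluster holding the majority of labeled-normal
    subjects is "normal"; the other is "abnormal". With both classes
    labeled, satisfied cannot-links already force them into distinct
    clusters, so the mapping is unambiguous."""
    normals = sorted(labeled.subsets.get(NORMAL, set()))
    if not normals:
        # only abnormal subjects labeled: anchor on them instead
        abnormals = sorted(labeled.subsets.get(ABNORMAL, set()))
        counts = np.bincount(assignment.labels[abnormals], minlength=len(assignment.centers))
        order = np.argsort(counts, kind="stable")
        if len(order) >= 2 and counts[order[-1]] == counts[order[-2]]:
            raise AmbiguousMappingError("ambiguous mapping: labeled subjects split evenly")
        ab_cluster = int(order[-1])
        return {c: (ABNORMAL if c == ab_cluster else NORMAL) for c in range(len(assignment.centers))}
    counts = np.bincount(assignment.labels[normals], minlength=len(assignment.centers))
    order = np.argsort(counts, kind="stable")
    if len(order) >= 2 and counts[order[-1]] == counts[order[-2]]:
        raise AmbiguousMappingError("ambiguous mapping: labeled normals split evenly")
    normal_cluster = int(order[-1])
    return {c: (NORMAL if c == normal_cluster else ABNORMAL) for c in range(len(assignment.centers))}


@dataclass
class BCResult:
    """Outcome of one boundary-clamped constrained clustering step."""

    new_label: str
    clamped: bool
    assignment: ClusterAssignment | None  # None when clamped
    class_labels: dict[int, str] | None  # per-subject-index classes (clustering runs only)

    @property
    def n_distance_evals(self) -> int:
        return 0 if self.assignment is None else self.assignment.n_distance_evals


def bc_cop_kmeans(
    points: list[FeatureVector],
    labeled: LabeledSets,
    new_index: int,
    seed: int = 0,
    max_iter: int = 100,
) -> BCResult:
    """Classify the newest subject: clamp if its features sit inside exactly
    one labeled class's bounds; otherwise run COP-K-means (K=2) over all
    involved subjects with constraints generated from the labeled sets and
    map clusters to classes.

    On a clamp the clustering step is skipped entirely — previously
    assigned subjects keep their labels and no distances are computed.
    """
    bounds = compute_bounds(points, labeled)
    clamped_label = boundary_clamp(points[new_index], bounds)
    if clamped_label is not None:
        return BCResult(new_label=clamped_label, clamped=True, assignment=None, class_labels=None)
    constraints = generate_constraints(labeled)
    assignment = cop_kmeans(points, K=2, constraints=constraints, seed=seed, max_iter=max_iter)
    cluster_to_class = map_clusters(assignment, labeled)
    class_labels = {
        i: cluster_to_class[int(c)] for i, c in enumerate(assignment.labels)
    }
    return BCResult(
        new_label=class_labels[new_index],
        clamped=False,
        assignment=assignment,
        class_labels=class_labels,
    )
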