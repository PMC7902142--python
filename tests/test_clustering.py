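"""Constraint generation, COP-K-means, boundary clamping and the combined
classifier."""

import itertools

import numpy as np
import pytest

from gaitanomaly.clustering import (
    bc_cop_kmeans,
    boundary_clamp,
    compute_bounds,
    cop_kmeans,
    generate_constraints,
    map_clusters,
)
from gaitanomaly.errors import (
    AmbiguousMappingError,
    ConstraintViolationError,
    InconsistentLabelsError,
    UnknownSubjectError,
)
from gaitanomaly.types import (
    ABNORMAL,
    NORMAL,
    ClusterAssignment,
    ConstraintSet,
    FeatureVector,
    LabeledSets,
)

from oracles import best_constrained_bipartition, wcss


def fv(mean, std, sid=""):
    return FeatureVector(mean=mean, std=std, subject_id=sid)


def random_consistent_instance(rng, n_max=30, d=2):
    """Random points plus constraints derived from a hidden bipartition,
    so a feasible assignment always exists."""
    n = int(rng.integers(4, n_max + 1))
    X = rng.random((n, d))
    truth = rng.integers(0, 2, n)
    if len(np.unique(truth)) < 2:
        truth[0] = 1 - truth[1]
    must, cannot = [], []
    n_pairs = int(rng.integers(1, max(2, n // 2)))
    for _ in range(n_pairs):
        a, b = rng.choice(n, size=2, replace=False)
        (must if truth[a] == truth[b] else cannot).append((int(a), int(b)))
    return X, ConstraintSet.build(must, cannot)


def violations(labels, constraints):
    v = sum(1 for a, b in constraints.must_links if labels[a] != labels[b])
    v += sum(1 for a, b in constraints.cannot_links if labels[a] == labels[b])
    return v


class TestGenerateConstraints:
    def test_two_class_enumeration(self):
        labeled = LabeledSets({NORMAL: {0, 1}, ABNORMAL: {2}})
        cs = generate_constraints(labeled)
        assert cs.must_links == {(0, 1)}
        assert cs.cannot_links == {(0, 2), (1, 2)}

    def test_single_singleton_class(self):
        cs = generate_constraints(LabeledSets({NORMAL: {0}}))
        assert not cs.must_links and not cs.cannot_links

    def test_counts_match_pair_enumeration(self):
        labeled = LabeledSets({NORMAL: {0, 1, 2}, ABNORMAL: {3, 4}})
        cs = generate_constraints(labeled)
        assert len(cs.must_links) == 3 + 1  # C(3,2) + C(2,2)
        assert len(cs.cannot_links) == 3 * 2

    def test_overlapping_subsets_rejected(self):
        with pytest.raises(InconsistentLabelsError):
            LabeledSets({NORMAL: {0, 1}, ABNORMAL: {1}})


class TestCopKmeans:
    def test_well_separated_pairs(self):
        X = np.array([[0.0], [0.1], [10.0], [10.1]])
        res = cop_kmeans(X, K=2, seed=0)
        oracle_labels, oracle_obj = best_constrained_bipartition(X)
        assert res.converged
        assert res.inertia == pytest.approx(oracle_obj)
        assert res.labels[0] == res.labels[1] != res.labels[2] == res.labels[3]

    def test_cannot_link_splits_identical_points(self):
        X = np.array([[0.5, 0.5], [0.5, 0.5]])
        cs = ConstraintSet.build(cannot_links=[(0, 1)])
        res = cop_kmeans(X, K=2, constraints=cs, seed=0)
        assert res.labels[0] != res.labels[1]

    def test_must_link_drags_borderline_point(self):
        """A point nearer cluster A but must-linked into cluster B ends up
        in B, unlike unconstrained K-means."""
        X = np.array([[0.0], [0.1], [0.2], [1.0], [1.1], [1.2], [0.45]])
        free = cop_kmeans(X, K=2, seed=3)
        assert free.labels[6] == free.labels[0]  # nearer the low cluster
        cs = ConstraintSet.build(must_links=[(6, 3)])
        res = cop_kmeans(X, K=2, constraints=cs, seed=3)
        assert violations(res.labels, cs) == 0
        assert res.labels[6] == res.labels[3]

    def test_infeasible_constraints_fail_after_restarts(self):
        # cannot-link triangle is unsatisfiable with K=2
        X = np.random.default_rng(0).random((3, 2))
        cs = ConstraintSet.build(cannot_links=[(0, 1), (1, 2), (0, 2)])
        with pytest.raises(ConstraintViolationError):
            cop_kmeans(X, K=2, constraints=cs, seed=0, n_restarts=3)

    def test_deterministic_under_fixed_seed(self, rng):
        X, cs = random_consistent_instance(rng, n_max=15)
        a = cop_kmeans(X, K=2, constraints=cs, seed=11)
        b = cop_kmeans(X, K=2, constraints=cs, seed=11)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.centers, b.centers)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            cop_kmeans(np.zeros((1, 2)), K=2)

    def test_converged_runs_satisfy_all_constraints(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            X, cs = random_consistent_instance(rng, n_max=20)
            res = cop_kmeans(X, K=2, constraints=cs, seed=int(rng.integers(1000)))
            assert violations(res.labels, cs) == 0

    def test_matches_exhaustive_bipartition_on_small_instances(self):
        """Best-of-seeds constrained WCSS equals the exhaustive optimum on
        most small random instances."""
        rng = np.random.default_rng(9)
        hits = 0
        n_inst = 20
        for _ in range(n_inst):
            X, cs = random_consistent_instance(rng, n_max=8)
            best = min(
                cop_kmeans(X, K=2, constraints=cs, seed=s).inertia for s in range(20)
            )
            oracle = best_constrained_bipartition(
                X, must=cs.must_links, cannot=cs.cannot_links
            )
            assert oracle is not None
            if best <= oracle[1] * (1 + 1e-9) + 1e-12:
                hits += 1
        assert hits >= int(0.95 * n_inst)


class TestBoundsAndClamp:
    def test_singleton_bounds(self):
        pts = [fv(0.3, 0.1)]
        b = compute_bounds(pts, LabeledSets({NORMAL: {0}}))
        mins, maxs = b.boxes[NORMAL]
        assert np.array_equal(mins, [0.3, 0.1]) and np.array_equal(maxs, [0.3, 0.1])

    def test_componentwise_min_max(self):
        pts = [fv(0.2, 0.1), fv(0.4, 0.05)]
        b = compute_bounds(pts, LabeledSets({NORMAL: {0, 1}}))
        mins, maxs = b.boxes[NORMAL]
        assert np.array_equal(mins, [0.2, 0.05]) and np.array_equal(maxs, [0.4, 0.1])

    def test_labeled_member_inside_own_box(self, rng):
        pts = [fv(*rng.random(2)) for _ in range(6)]
        labeled = LabeledSets({NORMAL: {0, 1, 2}, ABNORMAL: {3, 4}})
        b = compute_bounds(pts, labeled)
        for lab, idxs in labeled.subsets.items():
            for i in idxs:
                assert b.contains(pts[i].as_array(), lab)

    def test_unknown_subject(self):
        with pytest.raises(UnknownSubjectError):
            compute_bounds([fv(0.1, 0.1)], LabeledSets({NORMAL: {0, 5}}))

    def test_clamp_inside_one_box(self):
        pts = [fv(0.2, 0.1), fv(0.4, 0.2), fv(0.8, 0.4), fv(0.9, 0.5)]
        b = compute_bounds(pts, LabeledSets({NORMAL: {0, 1}, ABNORMAL: {2, 3}}))
        assert boundary_clamp(fv(0.3, 0.15), b) == NORMAL
        assert boundary_clamp(fv(0.85, 0.45), b) == ABNORMAL

    def test_clamp_outside_all_boxes(self):
        b = compute_bounds([fv(0.2, 0.1), fv(0.4, 0.2)], LabeledSets({NORMAL: {0, 1}}))
        assert boundary_clamp(fv(0.9, 0.9), b) is None

    def test_clamp_ambiguous_overlapping_boxes(self):
        pts = [fv(0.0, 0.0), fv(1.0, 1.0), fv(0.4, 0.4), fv(0.6, 0.6)]
        b = compute_bounds(pts, LabeledSets({NORMAL: {0, 1}, ABNORMAL: {2, 3}}))
        assert boundary_clamp(fv(0.5, 0.5), b) is None  # inside both boxes

    def test_boundary_membership_is_inclusive(self):
        b = compute_bounds([fv(0.2, 0.1), fv(0.4, 0.2)], LabeledSets({NORMAL: {0, 1}}))
        assert boundary_clamp(fv(0.2, 0.2), b) == NORMAL  # on the box edge

    def test_labeled_points_never_clamp_to_other_class(self, rng):
        """With disjoint class boxes, a labeled point clamps to its own
        class or (never) to the other."""
        for _ in range(20):
            low = rng.uniform(0.0, 0.4, (4, 2))
            high = rng.uniform(0.6, 1.0, (4, 2))
            pts = [fv(*p) for p in np.vstack([low, high])]
            labeled = LabeledSets({NORMAL: {0, 1, 2, 3}, ABNORMAL: {4, 5, 6, 7}})
            b = compute_bounds(pts, labeled)
            for lab, idxs in labeled.subsets.items():
                for i in idxs:
                    assert boundary_clamp(pts[i], b) in (lab, None)


class TestMapClusters:
    def test_majority_rule(self):
        asg = ClusterAssignment(
            labels=np.array([1, 1, 0, 0]),
            centers=np.zeros((2, 2)),
            converged=True,
            n_iterations=1,
            inertia=0.0,
        )
        mapping = map_clusters(asg, LabeledSets({NORMAL: {0, 1}}))
        assert mapping == {1: NORMAL, 0: ABNORMAL}

    def test_two_class_mapping_forced_by_cannot_links(self):
        asg = ClusterAssignment(
            labels=np.array([0, 0, 1, 1, 0]),
            centers=np.zeros((2, 2)),
            converged=True,
            n_iterations=1,
            inertia=0.0,
        )
        mapping = map_clusters(asg, LabeledSets({NORMAL: {0, 1}, ABNORMAL: {2, 3}}))
        assert mapping == {0: NORMAL, 1: ABNORMAL}

    def test_even_split_ambiguous(self):
        asg = ClusterAssignment(
            labels=np.array([0, 1]),
            centers=np.zeros((2, 2)),
            converged=True,
            n_iterations=1,
            inertia=0.0,
        )
        with pytest.raises(AmbiguousMappingError):
            map_clusters(asg, LabeledSets({NORMAL: {0, 1}}))


class TestBCCopKmeans:
    def setup_method(self):
        # two tight populations; indices 0-1 labeled normal, 2 labeled abnormal
        self.pts = [
            fv(0.20, 0.10),
            fv(0.30, 0.15),
            fv(0.80, 0.40),
            fv(0.25, 0.12),
            fv(0.82, 0.41),
        ]
        self.labeled = LabeledSets({NORMAL: {0, 1}, ABNORMAL: {2}})

    def test_clamped_subject_skips_clustering(self):
        res = bc_cop_kmeans(self.pts, self.labeled, new_index=3, seed=0)
        assert res.clamped and res.new_label == NORMAL
        assert res.assignment is None
        assert res.n_distance_evals == 0

    def test_unclamped_subject_clusters_to_nearer_population(self):
        pts = self.pts + [fv(0.90, 0.48)]  # outside both boxes, near abnormal
        res = bc_cop_kmeans(pts, self.labeled, new_index=5, seed=0)
        assert not res.clamped
        assert res.new_label == ABNORMAL
        X = np.array([p.as_array() for p in pts])
        cs = generate_constraints(self.labeled)
        oracle = best_constrained_bipartition(X, cs.must_links, cs.cannot_links)
        assert res.assignment.inertia == pytest.approx(oracle[1])

    def test_single_class_clamp(self):
        pts = [fv(0.2, 0.1), fv(0.3, 0.2), fv(0.25, 0.15)]
        labeled = LabeledSets({NORMAL: {0, 1}})
        res = bc_cop_kmeans(pts, labeled, new_index=2, seed=0)
        assert res.clamped and res.new_label == NORMAL
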