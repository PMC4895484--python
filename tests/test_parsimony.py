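"""Event parsimony: DP optimum, optimal-labeling enumeration, fractional
weights, conflict detection, tree scoring and ranking.

The DP is cross-checked against a pure-Python exhaustive oracle that
enumerates every {1,2} completion independently of the implementation.
"""

import itertools

import numpy as np
import pytest

from breaktrace import (
    LabelMatrix,
    detect_conflict,
    enumerate_binary_unrooted_topologies,
    fractional_edge_weights,
    min_events,
    optimal_assignments,
    random_binary_unrooted_tree,
    rank_trees,
    read_newick,
    score_tree,
)
from breaktrace.parsimony import LabelingError, min_events_batch

from conftest import caterpillar7, oracle_assignment, oracle_min_events


def labels_for(tree, values):
    names = sorted(tree.leaf_names.values())
    return dict(zip(names, values))


class TestMinEvents:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ((2, 2, 2, 2, 2, 2, 2), 0),
            ((1, 2, 2, 2, 2, 2, 2), 1),
            ((3, 3, 3, 3, 3, 3, 3), 0),
        ],
    )
    def test_baseline_patterns(self, values, expected):
        t = caterpillar7()
        assert min_events(t, labels_for(t, values)) == expected

    def test_spec_tree_matches_exhaustive(self):
        t = read_newick("((1,2),(3,4),((5,6),7));")
        labels = labels_for(t, (1, 1, 2, 2, 1, 2, 3))
        assert min_events(t, labels) == oracle_min_events(t, labels)

    @pytest.mark.parametrize("N", [4, 5])
    def test_exhaustive_all_trees_all_patterns(self, N):
        for t in enumerate_binary_unrooted_topologies(N):
            for values in itertools.product((1, 2, 3), repeat=N):
                labels = labels_for(t, values)
                assert min_events(t, labels) == oracle_min_events(t, labels)

    @pytest.mark.parametrize("N", [6, 7])
    def test_random_trees_match_oracle(self, N):
        rng = np.random.default_rng(100 + N)
        for _ in range(25):
            t = random_binary_unrooted_tree(N, rng)
            values = rng.integers(1, 4, size=N)
            labels = labels_for(t, tuple(int(v) for v in values))
            assert min_events(t, labels) == oracle_min_events(t, labels)

    def test_wildcard_monotonicity(self):
        rng = np.random.default_rng(55)
        for _ in range(30):
            t = random_binary_unrooted_tree(6, rng)
            values = [int(v) for v in rng.integers(1, 3, size=6)]
            labels = labels_for(t, values)
            base = min_events(t, labels)
            for name in labels:
                relaxed = dict(labels)
                relaxed[name] = 3
                assert min_events(t, relaxed) <= base

    def test_connected_one_region_costs_one(self):
        # 1-leaves forming one side of an internal edge: exactly one event
        t = read_newick("((1,2),(3,4),((5,6),7));")
        labels = labels_for(t, (1, 1, 2, 2, 2, 2, 2))
        assert min_events(t, labels) == 1

    def test_missing_label_rejected(self):
        t = caterpillar7()
        with pytest.raises(LabelingError):
            min_events(t, {1: 2})

    def test_batch_matches_scalar(self):
        rng = np.random.default_rng(9)
        t = random_binary_unrooted_tree(7, rng)
        names = sorted(t.leaf_names.values())
        mat = rng.integers(1, 4, size=(40, 7)).astype(np.int8)
        batch = min_events_batch(t, mat, names)
        for i in range(40):
            assert batch[i] == min_events(t, dict(zip(names, (int(x) for x in mat[i]))))


class TestOptimalAssignments:
    def test_single_split_leaf_pendant_edge(self):
        t = read_newick("(1,2,(3,4));")
        a = optimal_assignments(t, {1: 1, 2: 2, 3: 2, 4: 2})
        assert a.event_number == 1
        assert a.optimal_labeling_count == 1
        # split stored as the side away from the smallest leaf
        assert a.candidate_splits == (frozenset({2, 3, 4}),)
        assert fractional_edge_weights(a) == {a.candidate_edges[0]: 1.0}

    def test_sister_cherry_internal_edge(self):
        t = read_newick("((1,2),3,(4,5));")
        a = optimal_assignments(t, {1: 1, 2: 1, 3: 2, 4: 2, 5: 2})
        assert a.event_number == 1
        assert frozenset({3, 4, 5}) in a.candidate_splits

    def test_wildcard_resolves_free_of_charge(self):
        t = read_newick("(1,2,(3,4));")
        a = optimal_assignments(t, {1: 2, 2: 2, 3: 2, 4: 3})
        assert a.event_number == 0
        assert a.candidate_edges == ()
        assert a.optimal_labeling_count == 1

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            t = random_binary_unrooted_tree(6, rng)
            values = tuple(int(v) for v in rng.integers(1, 4, size=6))
            labels = labels_for(t, values)
            a = optimal_assignments(t, labels)
            best, cand, count, fractions = oracle_assignment(t, labels)
            assert a.event_number == best
            assert set(a.candidate_edges) == cand
            assert a.optimal_labeling_count == count
            for e, f in a.edge_fractions.items():
                assert f == pytest.approx(fractions[e])

    def test_fraction_conservation(self):
        rng = np.random.default_rng(31)
        for _ in range(30):
            t = random_binary_unrooted_tree(7, rng)
            labels = labels_for(t, tuple(int(v) for v in rng.integers(1, 4, size=7)))
            a = optimal_assignments(t, labels)
            assert sum(a.edge_fractions.values()) == pytest.approx(a.event_number)
            assert all(f > 0 for f in a.edge_fractions.values())


class TestConflict:
    def test_no_split_no_conflict(self):
        t = caterpillar7()
        assert not detect_conflict(t, labels_for(t, (2,) * 7)).has_conflict

    def test_single_split_leaf_no_conflict(self):
        t = caterpillar7()
        assert not detect_conflict(t, labels_for(t, (1, 2, 2, 2, 2, 2, 2))).has_conflict

    def test_alternating_caterpillar_resolves_on_pendant_edges(self):
        # isolated split leaves can each be explained on their own pendant
        # edge, so no 1-vertex is forced onto a path between unsplit leaves
        t = caterpillar7()
        labels = labels_for(t, (2, 1, 2, 1, 2, 1, 2))
        report = detect_conflict(t, labels)
        assert not report.has_conflict
        assert min_events(t, labels) == 3

    def test_flanked_split_block_forces_conflict(self):
        # unsplit leaves at both ends of a caterpillar whose interior
        # leaves are all split: every optimal labeling puts 1s on the
        # spine, i.e. on the path between the two unsplit genomes
        t = caterpillar7()
        labels = labels_for(t, (2, 1, 1, 1, 1, 1, 2))
        report = detect_conflict(t, labels)
        assert report.has_conflict
        assert (1, 7) in report.offending_pairs
        assert min_events(t, labels) == 2


class TestScoringAndRanking:
    def make_matrix(self, rows, genomes, designated):
        labels = {}
        for sid, row in enumerate(rows):
            for g, v in zip(genomes, row):
                labels[(sid, g)] = v
        return LabelMatrix(labels, tuple(range(len(rows))), tuple(genomes), designated)

    def test_all_not_split_scores_zero(self):
        t = read_newick("(1,2,(3,4));")
        M = self.make_matrix([(2, 2, 2, 2)] * 3, (1, 2, 3, 4), 1)
        assert score_tree(t, M).total_events == 0

    def test_additive_over_scaffolds(self):
        t = read_newick("(1,2,(3,4));")
        M1 = self.make_matrix([(2, 1, 2, 1)], (1, 2, 3, 4), 1)
        M2 = self.make_matrix([(2, 2, 1, 1)], (1, 2, 3, 4), 1)
        M12 = self.make_matrix([(2, 1, 2, 1), (2, 2, 1, 1)], (1, 2, 3, 4), 1)
        assert (
            score_tree(t, M12).total_events
            == score_tree(t, M1).total_events + score_tree(t, M2).total_events
        )

    def test_class_counts_weighted_total(self):
        sim_rng = np.random.default_rng(3)
        t = random_binary_unrooted_tree(7, sim_rng)
        names = sorted(t.leaf_names.values())
        rows = [tuple(int(v) for v in sim_rng.integers(1, 4, size=7)) for _ in range(25)]
        rows = [(2,) + r[1:] for r in rows]  # designated column all 2
        M = self.make_matrix(rows, names, names[0])
        ts = score_tree(t, M)
        c = ts.scaffold_class_counts
        assert sum(c.values()) == 25
        if max(ts.per_scaffold) <= 3:
            assert ts.total_events == c[1] + 2 * c[2] + 3 * c[3]

    def test_leaf_mismatch_rejected(self):
        t = read_newick("(1,2,(3,5));")
        M = self.make_matrix([(2, 2, 2, 2)], (1, 2, 3, 4), 1)
        with pytest.raises(LabelingError):
            score_tree(t, M)

    def test_single_tree_ranks_first(self):
        t = read_newick("(1,2,(3,4));")
        M = self.make_matrix([(2, 1, 2, 2)], (1, 2, 3, 4), 1)
        assert rank_trees(M, [t], t).reference_rank == 1

    def test_all_ties_rank_one(self):
        trees = list(enumerate_binary_unrooted_topologies(4))
        M = self.make_matrix([(2, 2, 2, 2)], (1, 2, 3, 4), 1)
        for t in trees:
            assert rank_trees(M, trees, t).reference_rank == 1

    def test_quartet_recovers_generating_tree(self):
        # one inversion on the internal branch of ((1,2),(3,4)); whole
        # genome as a single scaffold: true quartet needs 1 event, the two
        # wrong quartets need 2
        from breaktrace import FragmentedGenome, Scaffold, apply_inversion
        from breaktrace import build_label_matrix, identity_genome

        g = identity_genome(30)
        inverted = apply_inversion(g, 8, 21)
        genomes = {1: g, 2: g, 3: inverted, 4: inverted}
        frag = FragmentedGenome((Scaffold(0, g.genes),), "1")
        M = build_label_matrix(frag, genomes, 1)
        trees = list(enumerate_binary_unrooted_topologies(4))
        ref = read_newick("((1,2),(3,4));")
        ranking = rank_trees(M, trees, ref)
        assert ranking.reference_total == 1
        assert ranking.reference_rank == 1
        assert sorted(t for _, t in ranking.entries) == [1, 2, 2]

    def test_reference_missing_rejected(self):
        trees = list(enumerate_binary_unrooted_topologies(4))
        M = self.make_matrix([(2, 2, 2, 2)], (1, 2, 3, 4), 1)
        with pytest.raises(LabelingError):
            rank_trees(M, trees[:1], trees[2])


class TestParameterRecovery:
    def test_true_branch_usually_among_candidates(self):
        # sparse regime (one inversion per branch, many scaffolds): the
        # branch of a true event should appear in some scaffold's candidate
        # set on the true tree for the large majority of events
        from breaktrace.experiments import (
            ExperimentConfig,
            _located_events,
            _simulate_and_label,
        )

        cfg = ExperimentConfig(
            n_genes=1000, k_per_branch=1, m_scaffolds=200, replicates=1, seed=17
        )
        located = total = 0
        for rep in range(10):
            sim, M = _simulate_and_label(cfg, 1, 200, rep)
            located += _located_events(sim, M)
            total += len(sim.events)
        assert located / total >= 0.9
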