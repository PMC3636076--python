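"""Binary coding, Jaccard dissimilarity, NJ reconstruction, duplicates."""

import numpy as np
import pytest
import skbio

from musadiv.distance_clustering import (
    DistanceMatrix,
    detect_duplicates,
    edge_splits,
    jaccard_dissimilarity,
    neighbor_joining,
    to_binary,
)
from musadiv.pipeline_io import GenotypeTable
from musadiv.validation import random_additive_tree, tree_distance_matrix


class TestToBinary:
    def test_identity_pattern_and_column_count(self):
        table = GenotypeTable(["x", "y"], ["L01"], [[(101,)], [(105,)]])
        b = to_binary(table)
        assert b.columns == [("L01", 101), ("L01", 105)]
        assert b.values.tolist() == [[1.0, 0.0], [0.0, 1.0]]

    def test_missing_locus_marks_all_its_columns(self, small_table):
        b = to_binary(small_table)
        l2_cols = [j for j, (l, _) in enumerate(b.columns) if l == "L02"]
        assert np.isnan(b.values[2, l2_cols]).all()
        l1_cols = [j for j, (l, _) in enumerate(b.columns) if l == "L01"]
        assert not np.isnan(b.values[2, l1_cols]).any()

    def test_column_count_is_sum_of_per_locus_distinct_alleles(self, small_table):
        b = to_binary(small_table)
        expected = sum(
            len({a for row in small_table.calls if row[j] is not None for a in row[j]})
            for j in range(small_table.n_loci)
        )
        assert len(b.columns) == expected


class TestJaccard:
    def test_identical_disjoint_and_half(self):
        table = GenotypeTable(
            ["i", "j", "k", "l"],
            ["L01", "L02"],
            [
                [(1, 2), (5,)],
                [(1, 2), (5,)],  # identical to i
                [(3,), (6,)],  # disjoint from i
                [(1, 3), (5,)],  # a=2 (alleles 1,5), b=1, c=1
            ],
        )
        d = jaccard_dissimilarity(to_binary(table))
        assert d.values[0, 1] == 0.0
        assert d.values[0, 2] == 1.0
        assert d.values[0, 3] == pytest.approx(0.5)

    def test_joint_absences_carry_no_signal(self):
        base = GenotypeTable(["i", "j"], ["L01"], [[(1,)], [(1, 2)]])
        padded = GenotypeTable(
            ["i", "j", "k"], ["L01"], [[(1,)], [(1, 2)], [(7, 8)]]
        )
        d0 = jaccard_dissimilarity(to_binary(base)).values[0, 1]
        d1 = jaccard_dissimilarity(to_binary(padded)).values[0, 1]
        assert d0 == pytest.approx(d1)

    def test_pair_without_shared_data_is_an_error(self):
        table = GenotypeTable(
            ["i", "j"], ["L01", "L02"], [[(1,), None], [None, (2,)]]
        )
        with pytest.raises(ValueError, match=r"\(i, j\)"):
            jaccard_dissimilarity(to_binary(table))


class TestDistanceMatrix:
    def test_asymmetry_rejected(self):
        m = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], m)

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(["a", "b"], np.array([[0.1, 1.0], [1.0, 0.0]]))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C"], d))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)

    def test_recovers_random_additive_trees(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            truth = random_additive_tree(int(rng.integers(4, 13)), rng)
            dm = tree_distance_matrix(truth)
            inferred = neighbor_joining(dm)
            s_true, s_inf = edge_splits(truth), edge_splits(inferred)
            assert set(s_true) == set(s_inf)
            for split, length in s_true.items():
                assert s_inf[split] == pytest.approx(length, abs=1e-9)

    def test_agrees_with_skbio_on_additive_data(self):
        rng = np.random.default_rng(3)
        truth = random_additive_tree(8, rng)
        dm = tree_distance_matrix(truth)
        ours = neighbor_joining(dm)
        theirs = skbio.tree.nj(
            skbio.DistanceMatrix(dm.values, ids=dm.labels)
        )
        assert set(edge_splits(ours)) == set(edge_splits(theirs))

    def test_equidistant_taxa_resolve_with_equal_tip_lengths(self):
        n = 5
        d = np.ones((n, n)) - np.eye(n)
        tree = neighbor_joining(DistanceMatrix(list("ABCDE"), d))
        tip_lengths = {t.length for t in tree.tips()}
        assert all(ln == pytest.approx(0.5) for ln in tip_lengths)

    def test_total_length_invariant_to_label_order(self):
        rng = np.random.default_rng(29)
        truth = random_additive_tree(7, rng)
        dm = tree_distance_matrix(truth)
        perm = rng.permutation(len(dm.labels))
        shuffled = DistanceMatrix(
            [dm.labels[i] for i in perm], dm.values[np.ix_(perm, perm)]
        )
        t1, t2 = neighbor_joining(dm), neighbor_joining(shuffled)
        total1 = sum(n.length or 0 for n in t1.traverse(include_self=False))
        total2 = sum(n.length or 0 for n in t2.traverse(include_self=False))
        assert total1 == pytest.approx(total2, abs=1e-9)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a", "b"], np.array([[0.0, 1], [1, 0.0]])))


class TestDuplicates:
    def test_identical_pair_reported_once(self):
        d = np.array([[0.0, 0.0, 0.4], [0.0, 0.0, 0.4], [0.4, 0.4, 0.0]])
        assert detect_duplicates(DistanceMatrix(["a", "b", "c"], d)) == [["a", "b"]]

    def test_no_zero_offdiagonal_gives_empty(self):
        d = np.array([[0.0, 0.1], [0.1, 0.0]])
        assert detect_duplicates(DistanceMatrix(["a", "b"], d)) == []

    def test_clone_group_of_three_is_transitively_grouped(self):
        labels = ["a", "b", "c", "d"]
        d = np.full((4, 4), 0.5)
        np.fill_diagonal(d, 0.0)
        for i, j in [(0, 1), (1, 2), (0, 2)]:
            d[i, j] = d[j, i] = 0.0
        groups = detect_duplicates(DistanceMatrix(labels, d))
        assert groups == [["a", "b", "c"]]
        pairs = [(x, y) for g in groups for k, x in enumerate(g) for y in g[k + 1:]]
        assert len(pairs) == 3
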