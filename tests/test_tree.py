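import numpy as np
import pytest

from teao.msa_io import Alignment
from teao.tree import (
    DistanceMatrix,
    cophenetic_matrix,
    pairwise_distance,
    tree_levels,
    upgma,
    write_newick,
)

from .oracles import brute_force_upgma


def random_dm(rng, n, integer=False):
    if integer:
        # small-integer entries provoke frequent exact ties
        m = rng.integers(1, 8, size=(n, n)).astype(float)
        m = np.triu(m, 1)
        m = m + m.T
    else:
        m = rng.random((n, n))
        m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return DistanceMatrix(labels=tuple(f"t{i}" for i in range(n)), d=m)


class TestPairwiseDistance:
    def test_identical_sequences(self):
        aln = Alignment(ids=("a", "b"), sequences=("ACDE", "ACDE"))
        assert pairwise_distance(aln).d[0, 1] == 0.0

    def test_one_mismatch_in_four(self):
        aln = Alignment(ids=("a", "b"), sequences=("AAAA", "AAAC"))
        assert pairwise_distance(aln).d[0, 1] == pytest.approx(0.25)

    def test_gaps_excluded_pairwise(self):
        # comparable columns are 1 and 3 only; both match -> distance 0
        aln = Alignment(ids=("a", "b"), sequences=("A-CD", "AAC-"))
        assert pairwise_distance(aln).d[0, 1] == 0.0

    def test_ambiguity_excluded_like_gaps(self):
        aln = Alignment(ids=("a", "b"), sequences=("AXCD", "AACD"))
        assert pairwise_distance(aln).d[0, 1] == 0.0

    def test_zero_overlap_pair_gets_one_with_warning(self, caplog):
        aln = Alignment(ids=("a", "b"), sequences=("AC--", "--DE"))
        with caplog.at_level("WARNING", logger="teao.tree"):
            dm = pairwise_distance(aln)
        assert dm.d[0, 1] == 1.0
        assert any("no comparable columns" in r.message for r in caplog.records)


class TestDistanceMatrixValidation:
    def test_nan_rejected(self):
        m = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError, match="NaN"):
            DistanceMatrix(labels=("a", "b"), d=m)

    def test_negative_rejected(self):
        m = np.array([[0.0, -0.1], [-0.1, 0.0]])
        with pytest.raises(ValueError, match="negative"):
            DistanceMatrix(labels=("a", "b"), d=m)

    def test_asymmetric_rejected(self):
        m = np.array([[0.0, 0.2], [0.3, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(labels=("a", "b"), d=m)


class TestUpgma:
    def test_three_taxa_hand_example(self):
        # d(A,B)=2, d(A,C)=d(B,C)=4 (scaled): merge {A,B} at height 1,
        # then all at height 2
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float) / 4.0
        dm = DistanceMatrix(labels=("A", "B", "C"), d=d)
        tree = upgma(dm)
        (a, b, h1), (_, _, h2) = tree.merges
        assert {a, b} == {0, 1}
        assert h1 == pytest.approx(2 / 4 / 2)
        assert h2 == pytest.approx(4 / 4 / 2)

    def test_two_leaves(self):
        dm = DistanceMatrix(labels=("A", "B"), d=np.array([[0, 0.2], [0.2, 0]]))
        tree = upgma(dm)
        assert len(tree.merges) == 1
        assert tree.merges[0][2] == pytest.approx(0.1)

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            tree = upgma(random_dm(rng, 7))
            hs = [h for _, _, h in tree.merges]
            assert all(a <= b + 1e-12 for a, b in zip(hs, hs[1:]))

    def test_cophenetic_ultrametric(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            tree = upgma(random_dm(rng, 6))
            coph = cophenetic_matrix(tree)
            n = 6
            for i in range(n):
                for j in range(n):
                    for k in range(n):
                        assert coph[i, j] <= max(coph[i, k], coph[j, k]) + 1e-9

    def test_matches_scipy_average_linkage_without_ties(self):
        """Independent cross-check: same heights as scipy's UPGMA."""
        from scipy.cluster.hierarchy import average
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(3)
        for _ in range(10):
            dm = random_dm(rng, 8)  # continuous entries: ties a.s. absent
            tree = upgma(dm)
            Z = average(squareform(dm.d, checks=False))
            ours = sorted(h for _, _, h in tree.merges)
            scipys = sorted(Z[:, 2] / 2.0)
            assert np.allclose(ours, scipys)


class TestBruteForceOracle:
    @pytest.mark.parametrize("n", [3, 5, 8])
    def test_oracle_equivalence_heights_and_partitions(self, n):
        rng = np.random.default_rng(42)
        for _ in range(25):
            dm = random_dm(rng, n, integer=True)
            tree = upgma(dm)
            merges, oracle_parts = brute_force_upgma(dm.labels, dm.d)
            assert [h for _, _, h in tree.merges] == pytest.approx(
                [h for _, _, h in merges]
            )
            parts = tree_levels(tree)
            for k in range(1, n + 1):
                got = {
                    frozenset(
                        dm.labels.index(i) for i in grp
                    )
                    for grp in parts.groups(k)
                }
                assert got == oracle_parts[k]


class TestTreeLevels:
    def test_refinement_chain(self):
        rng = np.random.default_rng(9)
        dm = random_dm(rng, 7)
        parts = tree_levels(upgma(dm))
        for k in range(1, 7):
            coarse = parts.groups(k)
            fine = parts.groups(k + 1)
            for f in fine:
                assert any(set(f) <= set(c) for c in coarse)

    def test_boundary_levels(self):
        rng = np.random.default_rng(2)
        dm = random_dm(rng, 5)
        parts = tree_levels(upgma(dm))
        assert len(parts.groups(1)) == 1
        assert len(parts.groups(5)) == 5
        assert set(parts.levels[1].values()) == {0}

    def test_hand_example_level_two(self):
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float) / 4
        parts = tree_levels(upgma(DistanceMatrix(labels=("A", "B", "C"), d=d)))
        assert sorted(map(sorted, parts.groups(2))) == [["A", "B"], ["C"]]

    def test_label_invariance_under_permutation(self):
        """Permuting the input rows leaves every level's label partition
        unchanged."""
        rng = np.random.default_rng(17)
        base = random_dm(rng, 6, integer=True)
        perm = rng.permutation(6)
        permuted = DistanceMatrix(
            labels=tuple(base.labels[p] for p in perm),
            d=base.d[np.ix_(perm, perm)],
        )
        p1 = tree_levels(upgma(base))
        p2 = tree_levels(upgma(permuted))
        for k in range(1, 7):
            s1 = {frozenset(g) for g in p1.groups(k)}
            s2 = {frozenset(g) for g in p2.groups(k)}
            assert s1 == s2


class TestNewick:
    def test_two_leaf_string(self):
        dm = DistanceMatrix(labels=("A", "B"), d=np.array([[0, 0.2], [0.2, 0]]))
        assert write_newick(upgma(dm)) == "(A:0.1,B:0.1);"

    def test_three_leaf_string(self):
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        dm = DistanceMatrix(labels=("A", "B", "C"), d=d)
        assert write_newick(upgma(dm)) == "((A:1,B:1):1,C:2);"

    def test_round_trips_through_dendropy(self, tmp_path):
        import dendropy

        rng = np.random.default_rng(23)
        dm = random_dm(rng, 6)
        tree = upgma(dm)
        text = write_newick(tree, tmp_path / "t.nwk")
        parsed = dendropy.Tree.get(data=text, schema="newick")
        taxa = {leaf.taxon.label for leaf in parsed.leaf_node_iter()}
        assert taxa == set(dm.labels)
        # clades match: compare leaf-set bipartitions
        our_clades = {
            frozenset(tree.labels[l] for l in tree.leaves_below(n))
            for n in range(tree.n_leaves, 2 * tree.n_leaves - 1)
        }
        dp_clades = {
            frozenset(lf.taxon.label for lf in nd.leaf_iter())
            for nd in parsed.preorder_internal_node_iter()
        }
        assert our_clades == dp_clades

    def test_labels_needing_quotes_are_escaped(self):
        dm = DistanceMatrix(
            labels=("needs space", "ok"), d=np.array([[0, 0.4], [0.4, 0]])
        )
        text = write_newick(upgma(dm))
        assert "'needs space'" in text
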