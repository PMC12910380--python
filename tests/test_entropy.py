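import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from teao.entropy import (
    MAX_ENTROPY,
    global_profile,
    level_average_profile,
    profile_table,
    shannon_entropy,
    teao_profile,
)
from teao.fixtures import default_spec, generate_msa
from teao.msa_io import Alignment, map_reference_positions
from teao.tree import pairwise_distance, tree_levels, upgma

from .conftest import random_alignment
from .oracles import column_entropy, level_average


def teao_for(aln):
    return teao_profile(aln, tree_levels(upgma(pairwise_distance(aln))))


class TestShannonEntropy:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ({"A": 10}, 0.0),                 # fully conserved
            ({"A": 5, "C": 5}, 1.0),          # uniform binary
            ({"A": 2, "C": 1, "D": 1}, 1.5),  # -[.5*log.5 + 2*.25*log.25]
            ({"A": 1}, 0.0),                  # single observation
            ({}, 0.0),                        # nothing observed
        ],
    )
    def test_closed_forms(self, counts, expected):
        assert shannon_entropy(counts) == pytest.approx(expected)

    def test_uniform_twenty_residues_hits_max(self):
        counts = {aa: 1 for aa in "ACDEFGHIKLMNPQRSTVWY"}
        assert shannon_entropy(counts) == pytest.approx(MAX_ENTROPY)

    @given(
        st.dictionaries(
            st.sampled_from(list("ACDEFGHIKLMNPQRSTVWY")),
            st.integers(min_value=0, max_value=50),
            max_size=20,
        )
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bounds_and_zero_iff_degenerate(self, counts):
        h = shannon_entropy(counts)
        assert 0.0 <= h <= MAX_ENTROPY + 1e-12
        distinct = sum(1 for v in counts.values() if v > 0)
        total = sum(counts.values())
        if distinct <= 1 or total <= 1:
            assert h == 0.0
        elif distinct >= 2:
            assert h > 0.0


class TestGlobalProfile:
    def test_identical_rows_all_zero(self):
        aln = Alignment(ids=("a", "b", "c"), sequences=("ACDE",) * 3)
        assert np.all(global_profile(aln) == 0.0)

    def test_matches_brute_force_on_random_msa(self):
        rng = np.random.default_rng(31)
        aln = random_alignment(rng, n=15, L=40)
        prof = global_profile(aln)
        for c in range(aln.n_columns):
            col = "".join(s[c] for s in aln.sequences)
            assert prof[c] == pytest.approx(column_entropy(col))

    def test_gap_as_symbol_changes_ragged_columns(self):
        aln = Alignment(ids=("a", "b"), sequences=("A-", "AA"))
        assert global_profile(aln)[1] == 0.0
        assert global_profile(aln, gap_as_symbol=True)[1] == pytest.approx(1.0)


class TestLevelAverageProfile:
    def test_single_group_equals_global(self, toy_aln):
        part = {i: 0 for i in toy_aln.ids}
        np.testing.assert_allclose(
            level_average_profile(toy_aln, part), global_profile(toy_aln)
        )

    def test_singletons_all_zero(self, toy_aln):
        part = {ident: i for i, ident in enumerate(toy_aln.ids)}
        assert np.all(level_average_profile(toy_aln, part) == 0.0)

    def test_two_conserved_subgroups_closed_form(self):
        # each half conserved on a different residue: within-group entropy 0,
        # global entropy 1 bit
        aln = Alignment(
            ids=("a", "b", "c", "d"), sequences=("A", "A", "C", "C")
        )
        part = {"a": 0, "b": 0, "c": 1, "d": 1}
        assert level_average_profile(aln, part)[0] == 0.0
        assert global_profile(aln)[0] == pytest.approx(1.0)

    def test_identifier_mismatch_raises(self, toy_aln):
        with pytest.raises(ValueError, match="identifiers"):
            level_average_profile(toy_aln, {"nope": 0})

    def test_matches_brute_force_on_random_partition(self):
        rng = np.random.default_rng(13)
        aln = random_alignment(rng, n=10, L=20)
        assignment = {ident: int(rng.integers(3)) for ident in aln.ids}
        got = level_average_profile(aln, assignment)
        groups = [
            [i for i, ident in enumerate(aln.ids) if assignment[ident] == g]
            for g in sorted(set(assignment.values()))
        ]
        cols = ["".join(s[c] for s in aln.sequences) for c in range(20)]
        expected = level_average(cols, groups)
        np.testing.assert_allclose(got, expected)


class TestTeaoProfile:
    def test_identical_sequences(self):
        aln = Alignment(ids=("a", "b", "c"), sequences=("ACDE",) * 3)
        prof = teao_for(aln)
        assert np.all(prof.H_global == 0.0)
        assert np.all(prof.H_avg == 0.0)
        assert np.all(prof.conservation == 1.0)
        assert np.all(prof.specificity == 0.0)

    def test_concavity_on_random_msas(self):
        rng = np.random.default_rng(77)
        for _ in range(5):
            aln = random_alignment(rng, n=9, L=15)
            prof = teao_for(aln)
            assert np.all(prof.H_avg <= prof.H_global + 1e-12)

    def test_level_average_non_increasing_along_refinement(self):
        rng = np.random.default_rng(78)
        aln = random_alignment(rng, n=8, L=12, gap_p=0.0, ambig_p=0.0)
        prof = teao_for(aln)
        per_level_mean = prof.H_level.mean(axis=1)
        assert np.all(np.diff(per_level_mean) <= 1e-12)

    def test_row_and_column_order_invariance(self):
        rng = np.random.default_rng(55)
        aln = random_alignment(rng, n=8, L=14)
        prof = teao_for(aln)
        rperm = rng.permutation(8)
        cperm = rng.permutation(14)
        shuffled = Alignment(
            ids=tuple(aln.ids[i] for i in rperm),
            sequences=tuple(
                "".join(aln.sequences[i][c] for c in cperm) for i in rperm
            ),
        )
        prof2 = teao_for(shuffled)
        np.testing.assert_allclose(prof2.H_global, prof.H_global[cperm])
        np.testing.assert_allclose(prof2.H_avg, prof.H_avg[cperm], atol=1e-12)
        np.testing.assert_allclose(
            prof2.specificity, prof.specificity[cperm], atol=1e-12
        )

    def test_planted_specific_columns_outrank_background(self):
        aln, truth = generate_msa(default_spec(seed=101))
        prof = teao_for(aln)
        planted = truth.loc[
            truth["class"] == "subfamily_specific", "column"
        ].to_numpy() - 1
        background = [c for c in range(100) if c not in set(planted)]
        assert prof.specificity[planted].min() > max(
            prof.specificity[c] for c in background
        )

    def test_planted_conserved_columns_have_conservation_one(self):
        aln, truth = generate_msa(default_spec(seed=102))
        prof = teao_for(aln)
        cons = truth.loc[truth["class"] == "conserved", "column"].to_numpy() - 1
        np.testing.assert_allclose(prof.conservation[cons], 1.0)

    def test_scores_within_unit_interval(self):
        rng = np.random.default_rng(91)
        aln = random_alignment(rng, n=10, L=30)
        prof = teao_for(aln)
        assert np.all((0 <= prof.conservation) & (prof.conservation <= 1))
        assert np.all((0 <= prof.specificity) & (prof.specificity <= 1))

    def test_inner_levels_drop_trivial_partitions(self):
        aln, _ = generate_msa(default_spec(seed=5))
        parts = tree_levels(upgma(pairwise_distance(aln)))
        full = teao_profile(aln, parts, levels="all")
        inner = teao_profile(aln, parts, levels="inner")
        n = aln.n_sequences
        expected = full.H_level[1 : n - 1].mean(axis=0)
        np.testing.assert_allclose(inner.H_avg, expected)

    def test_wrong_partition_set_rejected(self, toy_aln):
        aln2, _ = generate_msa(default_spec(seed=1))
        parts = tree_levels(upgma(pairwise_distance(aln2)))
        with pytest.raises(ValueError, match="different alignment"):
            teao_profile(toy_aln, parts)


def test_profile_table_layout(toy_aln):
    import pandas as pd

    prof = teao_for(toy_aln)
    pmap = map_reference_positions(toy_aln, "s3")  # has a gap at column 7
    df = profile_table(prof, pmap)
    assert list(df["column"]) == list(range(1, 9))
    assert pd.isna(df.loc[6, "reference_residue"])  # the reference gap
    assert {"H_global", "H_avg", "conservation", "specificity",
            "gap_fraction", "n_distinct", "low_support"} <= set(df.columns)
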