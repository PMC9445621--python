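"""Presence calling, prevalence / abundance statistics, niche overlap,
Bray-Curtis dissimilarity and the complete-linkage sample tree."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from _oracles import bray_curtis_pair, naive_agglomerative
from lactopan import (
    AbundanceTable,
    DissimilarityMatrix,
    abundance_variance,
    apply_presence_threshold,
    bray_curtis_matrix,
    complete_linkage_tree,
    mean_relative_abundance,
    niche_overlap,
    read_abundance,
    species_prevalence,
)
from lactopan.profiles import write_abundance


def make_table(values, species, niches):
    samples = [f"s{i}" for i in range(len(values))]
    return AbundanceTable(
        pd.DataFrame(values, index=samples, columns=species),
        pd.Series(niches, index=samples),
    )


@pytest.fixture
def two_niche_table():
    # 2 food + 2 human samples, 3 species, percent scale
    return make_table(
        [[25.0, 0.0, 10.0], [0.01, 5.0, 0.0], [0.0, 30.0, 0.0], [0.02, 0.0, 1.0]],
        ["sp_a", "sp_b", "sp_c"],
        ["food", "food", "human", "human"],
    )


class TestPresence:
    def test_strict_inequality_at_threshold(self, two_niche_table):
        presence = apply_presence_threshold(two_niche_table, 0.01)
        assert not presence.values.loc["s1", "sp_a"]  # exactly 0.01 -> absent
        assert presence.values.loc["s3", "sp_a"]  # 0.02 -> present

    def test_matches_brute_force_cell_scan(self):
        rng = np.random.default_rng(2)
        values = rng.uniform(0, 1, (20, 15))
        values = values / values.sum(axis=1, keepdims=True) * 100
        table = make_table(values, [f"sp{j}" for j in range(15)], ["food"] * 20)
        presence = apply_presence_threshold(table, 0.01)
        counts = presence.values.sum(axis=0)
        for j, sp in enumerate(table.species):
            assert counts[sp] == sum(values[i, j] > 0.01 for i in range(20))

    def test_negative_threshold_rejected(self, two_niche_table):
        with pytest.raises(ValueError):
            apply_presence_threshold(two_niche_table, -0.1)

    @given(st.floats(min_value=0.0, max_value=5.0), st.floats(min_value=0.0, max_value=5.0))
    @settings(max_examples=25, deadline=None)
    def test_presence_monotone_in_threshold(self, t1, t2):
        rng = np.random.default_rng(4)
        values = rng.uniform(0, 10, (8, 6))
        table = make_table(values, [f"sp{j}" for j in range(6)], ["x"] * 8)
        lo, hi = sorted([t1, t2])
        n_lo = apply_presence_threshold(table, lo).values.sum().sum()
        n_hi = apply_presence_threshold(table, hi).values.sum().sum()
        assert n_hi <= n_lo


class TestPrevalenceAndAbundance:
    def test_absent_species_zero_prevalence(self, two_niche_table):
        presence = apply_presence_threshold(two_niche_table)
        assert species_prevalence(presence, "sp_c", "human") == (1, 2, 0.5)
        assert species_prevalence(presence, "sp_b", "human") == (1, 2, 0.5)
        assert species_prevalence(presence, "sp_c", "food") == (1, 2, 0.5)
        # sp_a at exactly the threshold in s1 counts as absent
        assert species_prevalence(presence, "sp_a", "food") == (1, 2, 0.5)

    def test_unknown_species_or_niche_rejected(self, two_niche_table):
        presence = apply_presence_threshold(two_niche_table)
        with pytest.raises(KeyError):
            species_prevalence(presence, "nope", "food")
        with pytest.raises(KeyError):
            species_prevalence(presence, "sp_a", "soil")

    def test_constant_abundance_mean(self):
        table = make_table([[10.0], [10.0], [10.0]], ["sp"], ["food"] * 3)
        assert mean_relative_abundance(table, "sp", "food") == 10.0

    def test_positives_only_mean(self, two_niche_table):
        # food sp_a: 25.0 and 0.01; only 25.0 exceeds the 0.01 threshold
        assert mean_relative_abundance(
            two_niche_table, "sp_a", "food", positives_only=True
        ) == 25.0
        assert mean_relative_abundance(two_niche_table, "sp_a", "food") == pytest.approx(12.505)

    def test_empty_positive_selection_errors(self):
        table = make_table([[0.0], [0.0]], ["sp"], ["food"] * 2)
        with pytest.raises(ValueError, match="no positive"):
            mean_relative_abundance(table, "sp", "food", positives_only=True)

    def test_variance_constant_is_zero(self):
        table = make_table([[5.0], [5.0], [5.0]], ["sp"], ["food"] * 3)
        assert abundance_variance(table, "sp", "food") == pytest.approx(0.0, abs=1e-30)

    def test_variance_hand_arithmetic_fraction_scale(self):
        # abundances 0% and 100% -> fractions 0 and 1 -> var (n-1) = 0.5
        table = make_table([[0.0], [100.0]], ["sp"], ["food"] * 2)
        assert abundance_variance(table, "sp", "food") == pytest.approx(0.5)

    def test_variance_needs_two_samples(self):
        table = make_table([[5.0]], ["sp"], ["food"])
        with pytest.raises(ValueError):
            abundance_variance(table, "sp", "food")


class TestNicheOverlap:
    def test_identical_sets(self):
        table = make_table(
            [[50.0, 50.0], [60.0, 40.0]], ["sp1", "sp2"], ["food", "human"]
        )
        presence = apply_presence_threshold(table)
        assert niche_overlap(presence, "food", "human") == (2, 0, 0)

    def test_counts_partition_niche_species(self, two_niche_table):
        presence = apply_presence_threshold(two_niche_table)
        common, ua, ub = niche_overlap(presence, "food", "human")
        assert common + ua == len(presence.niche_species("food"))
        assert common + ub == len(presence.niche_species("human"))

    def test_unknown_niche_rejected(self, two_niche_table):
        presence = apply_presence_threshold(two_niche_table)
        with pytest.raises(KeyError):
            niche_overlap(presence, "food", "soil")


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        table = make_table([[30.0, 70.0], [30.0, 70.0]], ["a", "b"], ["x", "x"])
        assert bray_curtis_matrix(table).values.iloc[0, 1] == 0.0

    def test_disjoint_samples_one(self):
        table = make_table([[100.0, 0.0], [0.0, 100.0]], ["a", "b"], ["x", "x"])
        assert bray_curtis_matrix(table).values.iloc[0, 1] == 1.0

    def test_hand_arithmetic(self):
        table = make_table(
            [[0.5, 0.5, 0.0], [0.25, 0.25, 0.5]], ["a", "b", "c"], ["x", "x"]
        )
        assert bray_curtis_matrix(table).values.iloc[0, 1] == pytest.approx(0.5)

    def test_all_zero_pair_is_zero_with_warning(self):
        table = make_table([[0.0, 0.0], [0.0, 0.0]], ["a", "b"], ["x", "x"])
        with pytest.warns(RuntimeWarning, match="all-zero"):
            bc = bray_curtis_matrix(table)
        assert bc.values.iloc[0, 1] == 0.0

    @given(
        hnp.arrays(
            np.float64,
            shape=st.tuples(st.integers(2, 6), st.integers(1, 8)),
            elements=st.floats(min_value=0.0, max_value=10.0, allow_nan=False),
        )
    )
    @settings(max_examples=40, deadline=None)
    def test_symmetric_bounded_zero_diagonal(self, values):
        values = values / max(values.sum(axis=1).max(), 1.0) * 50  # keep rows <= 100
        table = make_table(values, [f"sp{j}" for j in range(values.shape[1])],
                           ["x"] * values.shape[0])
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            bc = bray_curtis_matrix(table).values.to_numpy()
        assert np.allclose(bc, bc.T)
        assert np.allclose(np.diag(bc), 0)
        assert bc.min() >= 0 and bc.max() <= 1

    def test_matches_pairwise_formula_oracle(self):
        rng = np.random.default_rng(8)
        values = rng.uniform(0, 5, (5, 7))
        table = make_table(values, [f"sp{j}" for j in range(7)], ["x"] * 5)
        bc = bray_curtis_matrix(table).values.to_numpy()
        for i in range(5):
            for j in range(5):
                assert bc[i, j] == pytest.approx(
                    bray_curtis_pair(values[i], values[j]), abs=1e-12
                )


class TestCompleteLinkageTree:
    def test_two_samples_join_at_distance(self):
        dm = DissimilarityMatrix(
            pd.DataFrame([[0.0, 0.4], [0.4, 0.0]], index=["a", "b"], columns=["a", "b"])
        )
        assert complete_linkage_tree(dm) == "(a:0.4,b:0.4);"

    def test_close_pair_joins_first(self):
        arr = np.array([[0.0, 0.1, 0.9], [0.1, 0.0, 0.9], [0.9, 0.9, 0.0]])
        dm = DissimilarityMatrix(pd.DataFrame(arr, index=list("ABC"), columns=list("ABC")))
        newick = complete_linkage_tree(dm)
        assert "(A:0.1,B:0.1)" in newick

    def test_merge_order_matches_naive_oracle(self):
        rng = np.random.default_rng(19)
        raw = rng.uniform(0.1, 1.0, (8, 8))
        dist = np.clip((raw + raw.T) / 2, 0, 1)
        np.fill_diagonal(dist, 0.0)
        labels = [f"s{i}" for i in range(8)]
        dm = DissimilarityMatrix(pd.DataFrame(dist, index=labels, columns=labels))
        from scipy.cluster.hierarchy import linkage

        z = linkage(dm.condensed(), method="complete")
        oracle = naive_agglomerative(dist, "complete")
        # same merge heights in the same order
        np.testing.assert_allclose(z[:, 2], [h for _, _, h in oracle], rtol=1e-12)
        # and non-decreasing
        assert (np.diff(z[:, 2]) >= -1e-12).all()
        # leaf set preserved in the newick text
        newick = complete_linkage_tree(dm)
        for lab in labels:
            assert lab in newick

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DissimilarityMatrix(
                pd.DataFrame([[0.0, 0.5], [0.4, 0.0]], index=["a", "b"], columns=["a", "b"])
            )


class TestIO:
    def test_round_trip(self, tmp_path, two_niche_table):
        write_abundance(two_niche_table, tmp_path / "ab.tsv", tmp_path / "niche.tsv")
        back = read_abundance(tmp_path / "ab.tsv", tmp_path / "niche.tsv")
        pd.testing.assert_frame_equal(back.values, two_niche_table.values)
        pd.testing.assert_series_equal(
            back.niche, two_niche_table.niche, check_names=False
        )
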