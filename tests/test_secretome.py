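"""NSAF, identification partition, differential abundance, candidate pool."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import welch_t
from conftest import make_counts
from secretracer.secretome import (
    SecretomeError,
    assemble_candidate_pool,
    compute_nsaf,
    differential_abundance,
    partition_identifications,
)


class TestNSAF:
    def test_single_protein_is_one(self):
        scm = make_counts({"a_1": [7], "a_2": [3], "b_1": [1], "b_2": [9]}, [123])
        nsaf = compute_nsaf(scm)
        assert np.allclose(nsaf.to_numpy(), 1.0)

    def test_hand_arithmetic_two_proteins(self):
        scm = make_counts({"a_1": [10, 10], "a_2": [10, 10],
                           "b_1": [10, 10], "b_2": [10, 10]}, [100, 200])
        nsaf = compute_nsaf(scm)
        assert np.allclose(nsaf["a_1"], [2 / 3, 1 / 3])

    def test_scale_invariance_by_seven(self):
        scm = make_counts({"a_1": [3, 5, 8], "a_2": [2, 2, 2],
                           "b_1": [1, 1, 1], "b_2": [4, 0, 4]}, [50, 100, 150])
        scaled = make_counts({"a_1": [21, 35, 56], "a_2": [2, 2, 2],
                              "b_1": [1, 1, 1], "b_2": [4, 0, 4]}, [50, 100, 150])
        pd.testing.assert_frame_equal(compute_nsaf(scm), compute_nsaf(scaled))

    def test_all_zero_sample_error_names_sample(self):
        scm = make_counts({"a_1": [1, 2], "a_2": [0, 0], "b_1": [1, 1], "b_2": [2, 2]},
                          [10, 20])
        with pytest.raises(SecretomeError, match="a_2"):
            compute_nsaf(scm)

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_columns_sum_to_one_property(self, data):
        n = data.draw(st.integers(2, 12))
        counts = data.draw(st.lists(
            st.lists(st.integers(0, 500), min_size=4, max_size=4),
            min_size=n, max_size=n))
        lengths = data.draw(st.lists(st.integers(1, 2000), min_size=n, max_size=n))
        cols = ["a_1", "a_2", "b_1", "b_2"]
        df = {c: [row[i] for row in counts] for i, c in enumerate(cols)}
        scm = make_counts(df, lengths)
        if (scm.counts.sum(axis=0) == 0).any():
            return
        nsaf = compute_nsaf(scm)
        assert np.allclose(nsaf.sum(axis=0), 1.0, atol=1e-9)
        assert (nsaf.to_numpy() >= 0).all()


class TestPartition:
    def test_worked_example_counts(self):
        """375 shared + 101 A-only + 139 B-only proteins -> 615 detected."""
        n = 375 + 101 + 139 + 10  # 10 never-detected rows
        a = np.zeros(n, dtype=int)
        b = np.zeros(n, dtype=int)
        a[:375] = b[:375] = 5
        a[375:476] = 3
        b[476:615] = 4
        scm = make_counts({"A_1": a, "A_2": a, "B_1": b, "B_2": b},
                          [100] * n)
        part = partition_identifications(scm)
        sizes = part.sizes()
        assert sizes["shared"] == 375
        assert sizes["exclusive_A"] == 101
        assert sizes["exclusive_B"] == 139
        assert sizes["detected"] == 615

    def test_all_shared_means_no_exclusives(self):
        scm = make_counts({"a_1": [1, 2], "a_2": [1, 2], "b_1": [3, 4], "b_2": [1, 1]},
                          [10, 10])
        part = partition_identifications(scm)
        assert part.exclusive["a"] == set() and part.exclusive["b"] == set()

    def test_undetected_protein_excluded_everywhere(self):
        scm = make_counts({"a_1": [1, 0], "a_2": [1, 0], "b_1": [1, 0], "b_2": [1, 0]},
                          [10, 10])
        part = partition_identifications(scm)
        assert "P001" not in part.detected

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_partition_property(self, data):
        n = data.draw(st.integers(1, 15))
        mat = data.draw(st.lists(
            st.lists(st.integers(0, 3), min_size=4, max_size=4), min_size=n, max_size=n))
        cols = ["a_1", "a_2", "b_1", "b_2"]
        scm = make_counts({c: [r[i] for r in mat] for i, c in enumerate(cols)}, [10] * n)
        reps = data.draw(st.integers(1, 2))
        part = partition_identifications(scm, min_detect_reps=reps)
        assert len(part.shared) + len(part.exclusive["a"]) + len(part.exclusive["b"]) \
            == len(part.detected)
        assert part.shared.isdisjoint(part.exclusive["a"])
        assert part.shared.isdisjoint(part.exclusive["b"])
        assert part.exclusive["a"].isdisjoint(part.exclusive["b"])


class TestDifferentialAbundance:
    def _scm(self, a_vals, b_vals, n_extra=3):
        """One protein of interest plus filler proteins to set the scale."""
        rows_a = np.vstack([a_vals, np.full((n_extra, len(a_vals)), 20)])
        rows_b = np.vstack([b_vals, np.full((n_extra, len(b_vals)), 20)])
        cols = {}
        for i in range(len(a_vals)):
            cols[f"a_{i + 1}"] = rows_a[:, i]
        for i in range(len(b_vals)):
            cols[f"b_{i + 1}"] = rows_b[:, i]
        return make_counts(cols, [100] * (1 + n_extra))

    def test_identical_groups_not_significant(self):
        scm = self._scm([5, 5, 5], [5, 5, 5])
        nsaf = compute_nsaf(scm)
        part = partition_identifications(scm)
        tab = differential_abundance(nsaf, scm, part, "a", "b")
        assert tab.loc["P000", "log2fc"] == pytest.approx(0.0)
        assert not tab.loc["P000", "significant"]

    def test_welch_p_matches_formula_oracle(self):
        scm = self._scm([12, 17, 9], [31, 42, 55])
        nsaf = compute_nsaf(scm)
        part = partition_identifications(scm)
        tab = differential_abundance(nsaf, scm, part, "a", "b")
        nz = nsaf.to_numpy()[nsaf.to_numpy() > 0]
        eps = 0.5 * nz.min()
        xa = np.log2(nsaf.loc["P000", ["a_1", "a_2", "a_3"]].to_numpy(float) + eps)
        xb = np.log2(nsaf.loc["P000", ["b_1", "b_2", "b_3"]].to_numpy(float) + eps)
        _, _, p = welch_t(xa, xb)
        assert tab.loc["P000", "pvalue"] == pytest.approx(p, abs=1e-10)

    def test_planted_difference_flagged(self):
        # many small filler proteins keep the compositional shift of the
        # NSAF normalizer negligible for the planted 4-fold protein
        rng = np.random.default_rng(0)
        base = rng.poisson(60, size=3)
        scm = self._scm(base * 4, base, n_extra=100)
        nsaf = compute_nsaf(scm)
        part = partition_identifications(scm)
        tab = differential_abundance(nsaf, scm, part, "a", "b")
        assert tab.loc["P000", "log2fc"] > 1.5
        assert tab.loc["P000", "significant"]

    def test_single_replicate_rejected(self):
        scm = make_counts({"a_1": [5], "b_1": [5], "b_2": [5]}, [10])
        nsaf_ok = make_counts({"a_1": [5], "a_2": [5], "b_1": [5], "b_2": [5]}, [10])
        with pytest.raises(SecretomeError, match="replicates"):
            differential_abundance(compute_nsaf(scm), scm,
                                   partition_identifications(scm), "a", "b")
        # sanity: two replicates per side is accepted
        differential_abundance(compute_nsaf(nsaf_ok), nsaf_ok,
                               partition_identifications(nsaf_ok), "a", "b")

    def test_raising_lfc_threshold_monotone(self):
        rng = np.random.default_rng(1)
        n = 60
        cols = {f"a_{r}": rng.poisson(40, n) + 1 for r in range(1, 4)}
        cols.update({f"b_{r}": rng.poisson(25, n) + 1 for r in range(1, 4)})
        scm = make_counts(cols, [100] * n)
        nsaf = compute_nsaf(scm)
        part = partition_identifications(scm)
        counts = [
            differential_abundance(nsaf, scm, part, "a", "b", lfc_threshold=th)
            ["significant"].sum()
            for th in (0.0, 0.5, 1.0, 1.5, 2.0)
        ]
        assert all(x >= y for x, y in zip(counts, counts[1:]))


class TestCandidatePool:
    def test_worked_example_pool_size(self):
        """115 shared-secreted + 29 exclusive-secreted -> pool of 144."""
        n = 375 + 101 + 139
        a = np.zeros(n, dtype=int)
        b = np.zeros(n, dtype=int)
        a[:375] = b[:375] = 5
        a[375:476] = 3
        b[476:] = 4
        scm = make_counts({"A_1": a, "A_2": a, "B_1": b, "B_2": b}, [100] * n)
        part = partition_identifications(scm)
        secreted = pd.Series(0, index=scm.counts.index)
        secreted.iloc[:115] = 1          # shared secreted
        secreted.iloc[375:375 + 29] = 1  # A-exclusive secreted
        secreted.iloc[476:476 + 16] = 1  # B-exclusive secreted (never in A pool)
        pool = assemble_candidate_pool(part, secreted, "A")
        assert len(pool) == 144
        assert (pool.table["provenance"] == "shared").sum() == 115
        assert (pool.table["provenance"] == "exclusive").sum() == 29

    def test_no_annotation_means_empty_pool(self):
        scm = make_counts({"a_1": [1, 2], "a_2": [1, 2], "b_1": [1, 2], "b_2": [1, 2]},
                          [10, 10])
        part = partition_identifications(scm)
        pool = assemble_candidate_pool(part, pd.Series(0, index=scm.counts.index), "a")
        assert len(pool) == 0

    def test_reference_exclusive_never_in_target_pool(self):
        scm = make_counts({"a_1": [1, 0], "a_2": [1, 0], "b_1": [1, 3], "b_2": [1, 3]},
                          [10, 10])
        part = partition_identifications(scm)
        pool = assemble_candidate_pool(part, pd.Series(1, index=scm.counts.index), "a")
        assert "P001" not in pool.ids and "P000" in pool.ids

    def test_exclusive_candidates_have_no_fold_change(self):
        scm = make_counts({"a_1": [2, 4], "a_2": [2, 4], "b_1": [2, 0], "b_2": [2, 0]},
                          [10, 10])
        part = partition_identifications(scm)
        nsaf = compute_nsaf(scm)
        stats_tab = differential_abundance(nsaf, scm, part, "a", "b")
        pool = assemble_candidate_pool(part, pd.Series(1, index=scm.counts.index), "a",
                                       stats_tab)
        assert np.isnan(pool.table.loc["P001", "log2fc"])
        assert np.isfinite(pool.table.loc["P000", "log2fc"])
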