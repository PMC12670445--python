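from itertools import combinations

import numpy as np
import pytest
from scipy.stats import mannwhitneyu, rankdata

from spotcoloc import (
    ProportionTable,
    dominant_type,
    enriched_spots,
    marker_test,
    normalize,
    subset_frequencies,
)
from spotcoloc.errors import DataConsistencyError

from conftest import make_spot_matrix


def props(matrix, types):
    matrix = np.asarray(matrix, dtype=float)
    return ProportionTable(
        barcodes=[f"bc{i}" for i in range(len(matrix))],
        cell_types=types,
        proportions=matrix,
    )


class TestProportionTable:
    def test_bad_row_sum(self):
        with pytest.raises(DataConsistencyError):
            props([[0.4, 0.4]], ["a", "b"])

    def test_duplicate_types(self):
        with pytest.raises(DataConsistencyError):
            props([[0.5, 0.5]], ["a", "a"])


class TestDominantType:
    def test_pure_spot(self):
        p = props([[1.0, 0.0, 0.0]], ["a", "b", "c"])
        assert dominant_type(p).tolist() == ["a"]

    def test_tie_break_lexicographic(self):
        p = props([[0.5, 0.5]], ["Macrophage", "Fibroblast"])
        labels = dominant_type(p)
        # oracle: smallest name among the argmax set
        row = p.proportions[0]
        expected = min(t for t, v in zip(p.cell_types, row) if v == row.max())
        assert labels[0] == expected == "Fibroblast"

    def test_random_rows_vs_bruteforce(self, rng):
        mat = rng.dirichlet(np.ones(4), size=50)
        p = props(mat, ["t3", "t1", "t4", "t2"])
        labels = dominant_type(p)
        for s in range(50):
            cands = [
                p.cell_types[j]
                for j in range(4)
                if mat[s, j] == mat[s].max()
            ]
            assert labels[s] == min(cands)
            assert mat[s, p.cell_types.index(labels[s])] == mat[s].max()


class TestEnrichedSpots:
    def test_threshold_zero_all(self, rng):
        mat = rng.dirichlet(np.ones(3), size=10)
        p = props(mat, ["a", "b", "c"])
        assert len(enriched_spots(p, "b", 0.0)) == 10

    def test_threshold_one_pure_only(self):
        p = props([[1.0, 0.0], [0.5, 0.5]], ["a", "b"])
        assert enriched_spots(p, "a", 1.0).tolist() == ["bc0"]

    def test_loop_oracle(self, rng):
        mat = rng.dirichlet(np.ones(3), size=20)
        p = props(mat, ["a", "b", "c"])
        got = set(enriched_spots(p, "c", 0.25))
        expected = {f"bc{s}" for s in range(20) if mat[s, 2] >= 0.25}
        assert got == expected

    def test_monotone_in_threshold(self, rng):
        mat = rng.dirichlet(np.ones(3), size=30)
        p = props(mat, ["a", "b", "c"])
        prev = None
        for thr in np.linspace(0, 1, 11):
            cur = set(enriched_spots(p, "a", thr))
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_unknown_type(self):
        p = props([[1.0]], ["a"])
        with pytest.raises(KeyError):
            enriched_spots(p, "zzz", 0.5)


class TestSubsetFrequencies:
    def test_single_label(self):
        s = subset_frequencies(["FB1"] * 5, ["day0"] * 5)
        assert s.frequencies.loc["day0", "FB1"] == 1.0
        assert s.counts.loc["day0", "FB1"] == 5

    def test_hand_fixture(self):
        labels = ["FB1", "FB1", "FB2", "FB1", "FB2", "FB2", "FB2", "FB3", "FB3", "FB3"]
        conds = ["day0"] * 4 + ["day19"] * 6
        s = subset_frequencies(labels, conds)
        assert s.counts.loc["day0", "FB1"] == 3
        assert s.counts.loc["day0", "FB2"] == 1
        assert s.frequencies.loc["day0", "FB1"] == pytest.approx(3 / 4)
        assert s.frequencies.loc["day19", "FB2"] == pytest.approx(3 / 6)
        assert s.frequencies.loc["day19", "FB3"] == pytest.approx(3 / 6)
        assert s.spots_per_condition.tolist() == [4, 6]
        assert s.total_spots() == 10

    def test_rows_sum_to_one(self, rng):
        labels = rng.choice(["a", "b", "c"], size=100)
        conds = rng.choice(["x", "y"], size=100)
        s = subset_frequencies(labels, conds)
        np.testing.assert_allclose(s.frequencies.sum(axis=1), 1.0, atol=1e-9)

    def test_declared_empty_condition(self):
        with pytest.raises(DataConsistencyError, match="zero spots"):
            subset_frequencies(["a"], ["day0"], all_conditions=["day0", "day19"])

    def test_length_mismatch(self):
        with pytest.raises(DataConsistencyError):
            subset_frequencies(["a", "b"], ["day0"])


def exact_two_sided_oracle(v1, v2):
    """Exhaustive enumeration over all group assignments of the pooled data,
    counting rank sums at least as far from expectation as observed."""
    pooled = list(v1) + list(v2)
    n1, n = len(v1), len(v1) + len(v2)
    ranks = rankdata(pooled)
    mu = n1 * (n + 1) / 2
    obs = ranks[:n1].sum()
    hits = total = 0
    for idx in combinations(range(n), n1):
        w = sum(ranks[i] for i in idx)
        total += 1
        if abs(w - mu) >= abs(obs - mu) - 1e-9:
            hits += 1
    return hits / total


class TestMarkerTest:
    def _matrix(self, values_by_gene, n_spots):
        counts = np.asarray(values_by_gene)
        assert counts.shape[1] == n_spots
        return normalize(make_spot_matrix(counts))

    def test_lfc_gate(self):
        # complete group separation (tiny p) but fold change below 0.25:
        # de-logged means ~12 vs ~10 give log2(13/11) ~ 0.24
        stable = np.full(24, 1000)
        shifted = np.array([12] * 12 + [10] * 12)
        m = self._matrix([stable, shifted], 24)
        group = np.arange(24) < 12
        out = marker_test(m, group)
        assert out.loc[1, "p_value"] < 0.01
        assert 0 < out.loc[1, "log2fc"] < 0.25
        assert not out.loc[1, "passes_lfc"]

    def test_passes_lfc_invariant(self, rng):
        counts = rng.integers(0, 40, size=(12, 24))
        counts[0] = 1  # avoid zero-total spots
        m = self._matrix(counts, 24)
        group = np.arange(24) < 12
        out = marker_test(m, group, lfc_threshold=0.25)
        np.testing.assert_array_equal(
            out["passes_lfc"].to_numpy(), (out["log2fc"].abs() > 0.25).to_numpy()
        )

    def test_identical_groups(self):
        vals = np.tile(np.array([3, 1, 4, 1, 5]), 2)
        m = self._matrix([vals, np.ones(10, dtype=int)], 10)
        group = np.arange(10) < 5
        out = marker_test(m, group)
        assert out.loc[0, "log2fc"] == pytest.approx(0.0)
        assert out.loc[0, "p_value"] > 0.99

    def test_flat_gene(self):
        # constant spot totals keep gene 0 flat after normalization
        up = [1, 2, 3, 4, 5, 6, 7, 8]
        down = [8, 7, 6, 5, 4, 3, 2, 1]
        m = self._matrix([[2] * 8, up, down], 8)
        out = marker_test(m, np.arange(8) < 4)
        assert out.loc[0, "p_value"] == 1.0
        assert out.loc[0, "log2fc"] == 0.0

    def test_empty_group_errors(self):
        m = self._matrix([[1, 2, 3]], 3)
        with pytest.raises(DataConsistencyError, match="non-empty"):
            marker_test(m, [True, True, True])

    def test_exact_p_vs_enumeration_oracle(self, rng):
        counts = rng.integers(0, 15, size=(5, 9))
        counts[0] = np.maximum(counts[0], 1)
        m = self._matrix(counts, 9)
        group = np.arange(9) < 4  # groups of 4 and 5 -> exact path
        out = marker_test(m, group)
        X = np.asarray(m.normalized.todense())
        for gi in range(5):
            if np.ptp(X[gi]) == 0:
                continue
            expected = exact_two_sided_oracle(X[gi, group], X[gi, ~group])
            assert out.loc[gi, "p_value"] == pytest.approx(expected, abs=1e-12)

    def test_asymptotic_close_to_exact_for_large_groups(self, rng):
        # tie-free continuous data, groups of 30: library exact recursion as
        # the reference for our normal-approximation path
        v = rng.normal(size=60)
        counts = np.round(np.abs(v) * 1000 + 1).astype(int).reshape(1, 60)
        m = self._matrix(counts, 60)
        group = np.arange(60) < 30
        out = marker_test(m, group)
        X = np.asarray(m.normalized.todense())[0]
        ref = mannwhitneyu(X[group], X[~group], alternative="two-sided", method="exact").pvalue
        assert out.loc[0, "p_value"] == pytest.approx(ref, abs=0.01)

    def test_bh_adjustment(self, rng):
        counts = rng.integers(0, 25, size=(20, 30))
        counts[0] = np.maximum(counts[0], 1)
        m = self._matrix(counts, 30)
        out = marker_test(m, np.arange(30) < 15)
        assert (out["p_adj"] >= out["p_value"] - 1e-12).all()

    def test_dirichlet_dominance_recovery(self, rng):
        """Concentrated Dirichlet mixtures: dominant_type recovers the planted
        dominant type in >= 99% of spots."""
        types = ["a", "b", "c"]
        n = 600
        planted = rng.integers(0, 3, size=n)
        mat = np.empty((n, 3))
        for s in range(n):
            alpha = np.ones(3)
            alpha[planted[s]] = 60.0
            mat[s] = rng.dirichlet(alpha)
        p = props(mat, types)
        labels = dominant_type(p)
        correct = np.mean([labels[s] == types[planted[s]] for s in range(n)])
        assert correct >= 0.99
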