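"""Percentile-rank transform, merges, and housekeeping references."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from targetscape import (
    ValidationError,
    collapse_probes,
    high_expression_call,
    hk_fraction_score,
    hk_reference,
    intersect_merge,
    rank_percentile,
    union_merge,
)

from conftest import make_matrix, make_percentiles


class TestRankPercentile:
    def test_strict_ordering(self):
        m = make_matrix([[5.0], [1.0], [3.0]])
        p = rank_percentile(m, seed=0)
        np.testing.assert_allclose(p.values["s0"], [1.0, 1 / 3, 2 / 3])

    def test_rank_range(self):
        m = make_matrix(np.random.default_rng(0).random((40, 5)))
        p = rank_percentile(m, seed=0)
        assert np.allclose(p.values.max(axis=0), 1.0)
        assert np.allclose(p.values.min(axis=0), 1 / 40)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_rank_bijection(self, seed):
        """Per sample, sorted percentiles are exactly (1/G, ..., 1)."""
        rng = np.random.default_rng(seed)
        vals = rng.integers(0, 5, size=(25, 4)).astype(float)  # many ties
        p = rank_percentile(make_matrix(vals), seed=seed)
        expected = np.arange(1, 26) / 25
        for col in p.values.columns:
            np.testing.assert_allclose(np.sort(p.values[col]), expected)

    def test_tie_break_uniform(self):
        """Two tied genes split ranks 50/50 across seeds."""
        m = make_matrix([[2.0], [2.0]])
        first_top = sum(
            rank_percentile(m, seed=s).values.iloc[0, 0] == 1.0
            for s in range(1000)
        )
        assert abs(first_top / 1000 - 0.5) < 0.05

    def test_scale_invariance_single_sample(self):
        rng = np.random.default_rng(5)
        vals = rng.random((30, 3))
        p1 = rank_percentile(make_matrix(vals), seed=9)
        vals2 = vals.copy()
        vals2[:, 1] *= 137.0
        p2 = rank_percentile(make_matrix(vals2), seed=9)
        pd.testing.assert_frame_equal(p1.values, p2.values)

    def test_missing_genes_excluded_from_denominator(self):
        vals = np.array([[1.0, 1.0], [2.0, np.nan], [3.0, 3.0]])
        p = rank_percentile(make_matrix(vals), seed=0)
        np.testing.assert_allclose(p.values["s1"], [0.5, np.nan, 1.0])

    def test_all_equal_sample_is_permutation(self):
        p = rank_percentile(make_matrix([[7.0], [7.0], [7.0]]), seed=1)
        assert sorted(p.values["s0"]) == pytest.approx([1 / 3, 2 / 3, 1.0])

    def test_empty_matrix_errors(self):
        with pytest.raises(ValidationError):
            rank_percentile(make_matrix(np.empty((0, 0))), seed=0)

    def test_deterministic_given_seed(self):
        m = make_matrix(np.random.default_rng(2).integers(0, 3, (20, 4)))
        p1 = rank_percentile(m, seed=42)
        p2 = rank_percentile(m, seed=42)
        pd.testing.assert_frame_equal(p1.values, p2.values)


class TestCollapseProbes:
    def test_highest_mean_probe_wins(self):
        m = make_matrix([[3.0, 3.0], [7.0, 7.0]], genes=["pA", "pB"])
        out = collapse_probes(m, {"pA": "X", "pB": "X"})
        assert list(out.values.index) == ["X"]
        np.testing.assert_allclose(out.values.loc["X"], [7.0, 7.0])

    def test_single_probe_unchanged(self):
        m = make_matrix([[4.0, 5.0]], genes=["p1"])
        out = collapse_probes(m, {"p1": "G"})
        np.testing.assert_allclose(out.values.loc["G"], [4.0, 5.0])

    def test_tie_broken_by_smallest_probe_id(self):
        m = make_matrix([[5.0, 1.0], [1.0, 5.0]], genes=["p2", "p1"])
        out = collapse_probes(m, {"p1": "G", "p2": "G"})
        np.testing.assert_allclose(out.values.loc["G"], [1.0, 5.0])  # p1 row

    def test_unmapped_probes_dropped(self):
        m = make_matrix([[1.0], [2.0]], genes=["pA", "pB"])
        out = collapse_probes(m, {"pA": "X"})
        assert list(out.values.index) == ["X"]

    def test_empty_mapping_errors(self):
        m = make_matrix([[1.0]])
        with pytest.raises(ValidationError):
            collapse_probes(m, {})


class TestMerges:
    def test_union_gene_set_and_missingness(self):
        m1 = make_matrix([[1.0], [2.0]], genes=["A", "B"], samples=["x"],
                         platform="microarray", study={"x": "S1"})
        m2 = make_matrix([[3.0], [4.0]], genes=["B", "C"], samples=["y"],
                         platform="microarray", study={"y": "S2"})
        out = union_merge([m1, m2])
        assert list(out.values.index) == ["A", "B", "C"]
        assert np.isnan(out.values.loc["C", "x"])
        assert np.isnan(out.values.loc["A", "y"])
        assert out.values.loc["B", "y"] == 3.0

    def test_union_single_input_identity(self):
        m = make_matrix([[1.0, 2.0]], genes=["A"], platform="microarray")
        out = union_merge([m])
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_union_inclusion_exclusion(self):
        sets = [["A", "B"], ["B", "C"], ["C", "A", "D"]]
        mats = [
            make_matrix(np.ones((len(g), 1)), genes=g, samples=[f"s{i}"],
                        platform="microarray", study={f"s{i}": f"S{i}"})
            for i, g in enumerate(sets)
        ]
        out = union_merge(mats)
        assert out.n_genes == len(set().union(*map(set, sets)))

    def test_duplicate_samples_error(self):
        m1 = make_matrix([[1.0]], genes=["A"], samples=["s"])
        m2 = make_matrix([[1.0]], genes=["B"], samples=["s"])
        with pytest.raises(ValidationError):
            union_merge([m1, m2])

    def test_intersect(self):
        m1 = make_matrix(np.ones((3, 1)), genes=["A", "B", "C"], samples=["x"])
        m2 = make_matrix(np.ones((3, 1)), genes=["B", "C", "D"], samples=["y"])
        out = intersect_merge([m1, m2])
        assert list(out.values.index) == ["B", "C"]

    def test_intersect_identical_sets(self):
        m1 = make_matrix(np.ones((2, 1)), genes=["A", "B"], samples=["x"])
        m2 = make_matrix(np.ones((2, 1)), genes=["A", "B"], samples=["y"])
        assert intersect_merge([m1, m2]).n_genes == 2

    def test_disjoint_intersection_errors(self):
        m1 = make_matrix(np.ones((2, 1)), genes=["A", "B"], samples=["x"])
        m2 = make_matrix(np.ones((1, 1)), genes=["C"], samples=["y"])
        with pytest.raises(ValidationError):
            intersect_merge([m1, m2])


class TestHousekeepingReference:
    def test_degenerate_distribution(self):
        p = make_percentiles(np.full((3, 4), 0.8), genes=["HK1", "HK2", "g"])
        ref = hk_reference(p, ["HK1", "HK2"])
        assert ref.pooled == pytest.approx((0.8, 0.8, 0.8))

    def test_pooled_is_median_of_two_studies(self):
        # study A housekeeping values uniform on a grid with p90=0.85,
        # study B shifted so p90=0.95; pooled p90 = median = 0.90
        grid_a = np.linspace(0.40, 0.90, 101)  # p90 = 0.40 + 0.9*0.50 = 0.85
        grid_b = np.linspace(0.50, 1.00, 101)  # p90 = 0.95
        vals = np.column_stack([grid_a, grid_b])
        p = make_percentiles(vals, genes=[f"HK{i}" for i in range(101)],
                             samples=["a", "b"],
                             study={"a": "A", "b": "B"})
        ref = hk_reference(p, [f"HK{i}" for i in range(101)])
        # percentile of an evenly spaced grid is exact at grid points
        assert ref.pooled.p90 == pytest.approx(0.90, abs=1e-9)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        p = make_percentiles(rng.random((30, 10)),
                             genes=[f"HK{i}" for i in range(30)])
        ref = hk_reference(p, [f"HK{i}" for i in range(30)])
        assert ref.pooled.p01 <= ref.pooled.p50 <= ref.pooled.p90

    def test_no_hk_genes_errors(self):
        p = make_percentiles([[0.5]])
        with pytest.raises(ValidationError):
            hk_reference(p, ["absent"])


class TestHkFractionScore:
    def test_fraction_above_90_of_100_housekeeping_genes(self):
        """A gene above 90 of 100 housekeeping genes scores 0.9."""
        hk_vals = np.arange(1.0, 101.0)  # 1..100
        gene_val = 90.5  # above 90 of them
        vals = np.concatenate([[gene_val], hk_vals])[:, None]
        genes = ["g"] + [f"HK{i}" for i in range(100)]
        m = make_matrix(vals, genes=genes, platform="microarray")
        s = hk_fraction_score(m, genes[1:])
        assert s.loc["g", "s0"] == pytest.approx(0.9)

    def test_extremes(self):
        hk = [f"HK{i}" for i in range(10)]
        vals = np.concatenate([[0.0, 100.0], np.arange(1.0, 11.0)])[:, None]
        m = make_matrix(vals, genes=["low", "hi"] + hk, platform="microarray")
        s = hk_fraction_score(m, hk)
        assert s.loc["low", "s0"] == 0.0
        assert s.loc["hi", "s0"] == 1.0

    def test_brute_force_oracle(self):
        """Vectorized score equals a direct pairwise comparison count."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            n_g = rng.integers(5, 21)
            n_hk = rng.integers(2, 11)
            n_s = rng.integers(1, 6)
            vals = rng.integers(0, 8, size=(n_g, n_s)).astype(float)
            genes = [f"g{i}" for i in range(n_g)]
            hk = genes[: min(n_hk, n_g)]
            m = make_matrix(vals, genes=genes, platform="microarray")
            s = hk_fraction_score(m, hk)
            for j in range(n_s):
                hk_col = vals[: len(hk), j]
                for i in range(n_g):
                    expect = np.sum(hk_col < vals[i, j]) / len(hk)
                    assert s.iloc[i, j] == expect

    def test_missing_hk_sample_warns(self):
        vals = np.array([[1.0, 2.0], [np.nan, 3.0]])
        m = make_matrix(vals, genes=["g", "HK1"], platform="microarray")
        with pytest.warns(UserWarning):
            s = hk_fraction_score(m, ["HK1"])
        assert np.isnan(s.loc["g", "s0"])
        assert s.loc["g", "s1"] == 0.0


class TestHighExpressionCall:
    def test_strictly_above_threshold(self):
        assert high_expression_call(0.95, 0.9)
        assert not high_expression_call(0.9, 0.9)  # equality is not high
        assert not high_expression_call(0.0, 0.5)

    def test_elementwise(self):
        s = pd.Series([0.1, 0.9, 0.95])
        out = high_expression_call(s, 0.9)
        assert list(out) == [False, False, True]
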