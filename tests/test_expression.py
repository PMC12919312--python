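"""Normalization chain and abundance filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from dualseed.expression import (
    ExpressionError,
    ExpressionMatrix,
    cumulative_abundance_filter,
    expressed_above,
    log2p1,
    normalize_counts,
    size_factors,
    to_fpkm,
    to_rpm,
)


def matrix(values, rows=None, cols=None, scale="raw_counts", lengths=None):
    values = np.asarray(values, dtype=float)
    rows = rows or [f"g{i}" for i in range(values.shape[0])]
    cols = cols or [f"s{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=rows, columns=cols)
    if lengths is not None:
        lengths = pd.Series(lengths, index=rows)
    return ExpressionMatrix(df, scale=scale, gene_lengths=lengths)


pos_counts = arrays(
    np.float64, (6, 4), elements=st.floats(0.5, 1e4), unique=False
)


class TestSizeFactors:
    def test_hand_example(self):
        m = matrix([[2, 4], [4, 8], [8, 16]])
        s = size_factors(m)
        assert s.to_numpy() == pytest.approx([2 / np.sqrt(8), 4 / np.sqrt(8)], rel=1e-6)

    def test_identical_columns_equal_factors(self):
        m = matrix([[3, 3, 3], [7, 7, 7]])
        assert size_factors(m).nunique() == 1

    @given(counts=pos_counts, c=st.floats(0.25, 4.0))
    @settings(deadline=None, max_examples=50)
    def test_scale_equivariance(self, counts, c):
        """Rescaling one sample's column by c rescales its relative factor by c.

        (All factors shift by c**(-1/n) through the geometric means, so the
        equivariance statement is about factor ratios.)
        """
        base = matrix(counts)
        scaled_values = counts.copy()
        scaled_values[:, 0] *= c
        scaled = matrix(scaled_values)
        s0, s1 = size_factors(base), size_factors(scaled)
        assert s1["s0"] / s1["s1"] == pytest.approx(c * s0["s0"] / s0["s1"], rel=1e-9)

    @given(counts=pos_counts)
    @settings(deadline=None, max_examples=50)
    def test_gene_permutation_invariance(self, counts):
        m = matrix(counts)
        perm = matrix(counts[::-1])
        assert np.allclose(size_factors(m).to_numpy(), size_factors(perm).to_numpy())

    @given(counts=pos_counts)
    @settings(deadline=None, max_examples=50)
    def test_direct_formula_oracle(self, counts):
        """s_j = median_i counts[i,j] / geometric_mean(counts[i,:])."""
        geo = np.exp(np.mean(np.log(counts), axis=1))
        expected = np.median(counts / geo[:, None], axis=0)
        assert np.allclose(size_factors(matrix(counts)).to_numpy(), expected)

    def test_all_zero_row_matrix_rejected(self):
        m = matrix([[0, 2], [3, 0]])
        with pytest.raises(ExpressionError, match="pre-filter"):
            size_factors(m)


class TestNormalizeChain:
    def test_normalize_divides_by_factor(self):
        m = matrix([[2, 4]])
        out = normalize_counts(m, pd.Series([1.0, 2.0], index=["s0", "s1"]))
        assert out.values.to_numpy().tolist() == [[2.0, 2.0]]
        assert out.scale == "size_normalized"

    def test_round_trip(self):
        m = matrix([[2, 4], [6, 8]])
        f = pd.Series([0.5, 2.0], index=["s0", "s1"])
        out = normalize_counts(m, f)
        assert np.allclose(out.values.mul(f, axis=1).to_numpy(), m.values.to_numpy())

    def test_scale_state_machine_rejects_double_application(self):
        m = matrix([[2, 4]])
        f = pd.Series([1.0, 1.0], index=["s0", "s1"])
        norm = normalize_counts(m, f)
        with pytest.raises(ExpressionError):
            normalize_counts(norm, f)
        rpm = to_rpm(norm)
        with pytest.raises(ExpressionError):
            to_rpm(rpm)
        logm = log2p1(rpm)
        with pytest.raises(ExpressionError):
            log2p1(logm)

    def test_fpkm_single_gene(self):
        # a 1000 bp gene holding all 1e6 normalized fragments -> FPKM 1e6
        m = matrix([[1e6]], scale="size_normalized", lengths=[1000])
        out = to_fpkm(m)
        assert out.values.iloc[0, 0] == pytest.approx(1e6)
        assert log2p1(out).values.iloc[0, 0] == pytest.approx(np.log2(1 + 1e6))

    def test_fpkm_length_inverse_proportionality(self):
        m = matrix([[50, 50], [50, 50]], scale="size_normalized", lengths=[1000, 2000])
        out = to_fpkm(m).values
        assert np.allclose(out.iloc[0] / out.iloc[1], 2.0)

    @given(counts=pos_counts)
    @settings(deadline=None, max_examples=50)
    def test_fpkm_matches_formula_oracle(self, counts):
        lengths = np.linspace(500, 3000, counts.shape[0])
        m = matrix(counts, scale="size_normalized", lengths=lengths)
        out = to_fpkm(m).values.to_numpy()
        expected = counts * 1e9 / lengths[:, None] / counts.sum(axis=0)[None, :]
        assert np.allclose(out, expected)

    def test_rpm_columns_sum_to_million(self):
        rng = np.random.default_rng(0)
        m = matrix(rng.integers(1, 1000, (20, 5)).astype(float), scale="size_normalized")
        out = to_rpm(m)
        assert np.allclose(out.values.sum(axis=0), 1e6)
        unchanged = matrix(np.full((4, 1), 2.5e5), scale="size_normalized")
        assert np.allclose(to_rpm(unchanged).values.to_numpy(), 2.5e5)

    def test_rpm_rejects_gene_lengths(self):
        m = matrix([[1.0, 2.0]], scale="size_normalized", lengths=[100])
        with pytest.raises(ExpressionError, match="RPM"):
            to_rpm(m)


class TestAbundanceFilter:
    def worked_example(self):
        # medians 50, 30, 15, 4, 1 across three identical samples
        vals = np.array([[50, 30, 15, 4, 1]] * 3, dtype=float).T
        return matrix(vals, rows=["g1", "g2", "g3", "g4", "g5"], scale="fpkm")

    def test_keeps_top_99_percent(self):
        report = cumulative_abundance_filter(self.worked_example(), 0.99)
        assert set(report.kept_ids) == {"g1", "g2", "g3", "g4"}
        assert report.dropped_ids == ("g5",)
        assert report.cumulative_fraction_at_cut == pytest.approx(0.99)

    def test_fraction_one_keeps_positive_rows(self):
        vals = np.array([[10, 5, 0]] * 2, dtype=float).T
        report = cumulative_abundance_filter(matrix(vals, scale="fpkm"), 1.0)
        assert set(report.kept_ids) == {"g0", "g1"}

    def test_single_row_always_kept(self):
        report = cumulative_abundance_filter(matrix([[5.0, 5.0]], scale="fpkm"), 0.5)
        assert len(report.kept_ids) == 1

    def test_ties_at_cut_kept_together(self):
        vals = np.array([[10, 1, 1, 1]] * 2, dtype=float).T
        report = cumulative_abundance_filter(matrix(vals, scale="fpkm"), 0.8)
        # cut falls on a median-1 row: all median-1 rows stay
        assert len(report.kept_ids) == 4

    @given(
        medians=st.lists(st.floats(0.1, 100), min_size=2, max_size=15),
        f1=st.floats(0.2, 0.9),
        f2=st.floats(0.2, 0.9),
    )
    @settings(deadline=None, max_examples=50)
    def test_monotone_in_fraction(self, medians, f1, f2):
        vals = np.array([medians, medians], dtype=float).T
        m = matrix(vals, scale="fpkm")
        lo, hi = sorted([f1, f2])
        assert set(cumulative_abundance_filter(m, lo).kept_ids) <= set(
            cumulative_abundance_filter(m, hi).kept_ids
        )

    def test_log_scale_rejected(self):
        m = matrix([[1.0, 2.0]], scale="log2p1")
        with pytest.raises(ExpressionError):
            cumulative_abundance_filter(m)


class TestExpressedAbove:
    def test_partition_and_boundary(self):
        vals = np.array([[0, 0, 0], [1.0, 1.0, 1.0], [2, 3, 4]], dtype=float)
        m = matrix(vals, rows=["zero", "edge", "high"], scale="log2p1")
        expressed, excluded = expressed_above(m, ["zero", "edge", "high", "absent"], 1.0)
        assert expressed == ["edge", "high"]  # boundary median == 1.0 is kept
        assert excluded == ["zero", "absent"]

    def test_planted_count_recovered(self):
        rng = np.random.default_rng(3)
        k, n = 7, 30
        vals = np.vstack([np.full((k, 4), 5.0), np.full((n - k, 4), 0.2)])
        vals += rng.uniform(0, 0.05, vals.shape)
        m = matrix(vals, scale="log2p1")
        expressed, _ = expressed_above(m, list(m.row_ids), 1.0)
        assert len(expressed) == k
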