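import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats
from statsmodels.stats.multitest import multipletests

from detargets import ExpressionTable, ValidationError
from detargets.diffexpr import (
    bh_adjust,
    call_de,
    collapse_probes_to_genes,
    de_statistics,
    differential_expression,
    down_genes,
    log2_transform,
    quantile_normalize,
    student_t_two_sample,
    up_genes,
)


def _table(matrix, groups=None):
    matrix = np.asarray(matrix, dtype=float)
    n, m = matrix.shape
    cols = [f"s{j}" for j in range(m)]
    if groups is None:
        groups = ["A"] * (m // 2) + ["B"] * (m - m // 2)
    values = pd.DataFrame(matrix, index=[f"g{i}" for i in range(n)],
                          columns=cols)
    return ExpressionTable(values, pd.Series(dict(zip(cols, groups))))


class TestQuantileNormalize:
    def test_rank_mean_hand_example(self):
        out = quantile_normalize(_table([[2, 4], [6, 8]]))
        np.testing.assert_allclose(out.values.to_numpy(), [[3, 3], [7, 7]])

    def test_identical_columns_are_fixed_point(self):
        out = quantile_normalize(_table([[1, 1], [2, 2]]))
        np.testing.assert_allclose(out.values.to_numpy(), [[1, 1], [2, 2]])

    def test_single_column_unchanged(self):
        values = pd.DataFrame({"s0": [5.0, 1.0, 3.0]}, index=list("abc"))
        table = ExpressionTable(values, pd.Series({"s0": "A"}))
        out = quantile_normalize(table)
        np.testing.assert_allclose(out.values["s0"], [5.0, 1.0, 3.0])

    def test_ties_get_average_of_reference_values(self):
        # column 0 has a tie at rank 1-2; reference = mean of sorted cols
        out = quantile_normalize(_table([[1, 10], [1, 20], [5, 30]]))
        ref = np.array([(1 + 10) / 2, (1 + 20) / 2, (5 + 30) / 2])
        tied = (ref[0] + ref[1]) / 2
        np.testing.assert_allclose(out.values.iloc[:, 0], [tied, tied, ref[2]])
        np.testing.assert_allclose(out.values.iloc[:, 1], ref)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(arrays(np.float64, (7, 4),
                  elements=st.floats(-50, 50, allow_nan=False),
                  unique=True))
    def test_idempotent_with_identical_column_distributions(self, mat):
        # tie-free columns: with ties the tie-averaged variant is only
        # approximately a projection (exercised against limma below)
        out1 = quantile_normalize(_table(mat))
        out2 = quantile_normalize(out1)
        np.testing.assert_allclose(out1.values.to_numpy(),
                                   out2.values.to_numpy(), atol=1e-12)
        cols = np.sort(out1.values.to_numpy(), axis=0)
        for j in range(1, cols.shape[1]):
            np.testing.assert_allclose(cols[:, 0], cols[:, j], atol=1e-12)
        means = out1.values.to_numpy().mean(axis=0)
        np.testing.assert_allclose(means, means[0], atol=1e-9)

    def test_matches_limma_reference_implementation(self, tmp_path):
        """Independent oracle: limma::normalizeQuantiles (ties averaged)."""
        mat = np.array([[2.0, 9.0, 4.0],
                        [2.0, 1.0, 8.0],
                        [5.0, 1.0, 1.5],
                        [7.0, 3.0, 1.5],
                        [0.5, 3.0, 6.0]])
        ours = quantile_normalize(_table(mat, groups=["A", "A", "B"]))
        np.savetxt(tmp_path / "m.txt", mat)
        script = textwrap.dedent("""
            suppressMessages(library(limma))
            m <- as.matrix(read.table(commandArgs(TRUE)[1]))
            write.table(normalizeQuantiles(m, ties=TRUE),
                        commandArgs(TRUE)[2], row.names=FALSE,
                        col.names=FALSE)
        """)
        (tmp_path / "qn.R").write_text(script)
        subprocess.run(["Rscript", str(tmp_path / "qn.R"),
                        str(tmp_path / "m.txt"), str(tmp_path / "out.txt")],
                       check=True, capture_output=True)
        expected = np.loadtxt(tmp_path / "out.txt")
        np.testing.assert_allclose(ours.values.to_numpy(), expected,
                                   atol=1e-10)


class TestLog2Transform:
    def test_powers_of_two(self):
        values = pd.DataFrame([[8.0, 1.0]], index=["g1"], columns=["s1", "s2"])
        table = ExpressionTable(values, pd.Series({"s1": "A", "s2": "B"}),
                                scale="linear")
        out = log2_transform(table)
        np.testing.assert_allclose(out.values.to_numpy(), [[3.0, 0.0]])
        assert out.scale == "log2"

    def test_rejects_log_scale_input(self, small_expr):
        with pytest.raises(ValidationError, match="linear"):
            log2_transform(small_expr)


class TestStudentT:
    def test_identical_groups_give_t0_p1(self):
        t, df, p = student_t_two_sample([1, 2, 3], [1, 2, 3])
        assert (t, df, p) == (0.0, 4.0, 1.0)

    def test_pooled_hand_example(self):
        t, df, p = student_t_two_sample([1, 2, 3], [4, 5, 6])
        assert df == 4.0
        assert t == pytest.approx(-3 / np.sqrt(2 / 3), rel=1e-12)
        assert p == pytest.approx(0.021312, abs=1e-5)

    def test_zero_variance_unequal_means_gives_inf_sentinel(self):
        t, df, p = student_t_two_sample([0, 0, 0], [1, 1, 1])
        assert t == -np.inf and p == 0.0

    def test_zero_variance_equal_means_gives_null(self):
        t, _, p = student_t_two_sample([2, 2], [2, 2])
        assert (t, p) == (0.0, 1.0)

    def test_fewer_than_two_per_group_is_error(self):
        with pytest.raises(ValidationError):
            student_t_two_sample([1], [2, 3])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-10, 10), min_size=2, max_size=6),
           st.lists(st.floats(-10, 10), min_size=2, max_size=6))
    def test_antisymmetric_in_group_order(self, a, b):
        t1, df1, p1 = student_t_two_sample(a, b)
        t2, df2, p2 = student_t_two_sample(b, a)
        assert df1 == df2
        assert t1 == pytest.approx(-t2, rel=1e-12, abs=1e-12)
        assert p1 == pytest.approx(p2, rel=1e-12, abs=1e-12)

    def test_matches_scipy_on_random_grid(self, rng):
        for _ in range(200):
            a = rng.normal(size=rng.integers(2, 8))
            b = rng.normal(size=rng.integers(2, 8))
            t, df, p = student_t_two_sample(a, b)
            ref = stats.ttest_ind(a, b, equal_var=True)
            assert t == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_welch_matches_scipy(self, rng):
        a = rng.normal(size=5)
        b = rng.normal(scale=4.0, size=3)
        t, df, p = student_t_two_sample(a, b, welch=True)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)


class TestBHAdjust:
    @pytest.mark.parametrize("p, expected", [
        ([0.03], [0.03]),
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.005, 0.049, 0.05], [0.015, 0.05, 0.05]),
    ])
    def test_step_up_hand_examples(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected, rtol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_output_dominates_input_and_is_capped(self, p):
        q = bh_adjust(p)
        assert (q >= np.asarray(p) - 1e-15).all()
        assert (q <= 1.0).all()
        # monotone in the sorted order of p
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_matches_statsmodels_on_random_vectors(self, rng):
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 60))
            expected = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), expected, rtol=1e-10)


class TestDECalls:
    def test_direction_rule_and_threshold(self):
        det = pd.DataFrame(
            {"diff": [1.0, -1.0, -2.0], "q_value": [0.01, 0.2, 0.04],
             "direction": ["up", "down", "down"], "is_de": False},
            index=pd.Index(["g1", "g2", "g3"], name="feature_id"),
        )
        out = call_de(det, 0.05)
        assert up_genes(out) == {"g1"}
        assert down_genes(out) == {"g3"}

    def test_q_exactly_at_threshold_is_not_de(self):
        det = pd.DataFrame(
            {"diff": [1.0], "q_value": [0.05], "direction": ["up"],
             "is_de": False},
            index=pd.Index(["g1"], name="feature_id"),
        )
        assert not call_de(det, 0.05)["is_de"].iloc[0]

    def test_empty_table_gives_empty_sets(self):
        det = pd.DataFrame(columns=["diff", "q_value", "direction", "is_de"])
        out = call_de(det, 0.05)
        assert up_genes(out) == set() and down_genes(out) == set()


def _probe_table(rows):
    det = pd.DataFrame(
        rows,
        columns=["mean_A", "mean_B", "diff", "t_stat", "df", "p_value",
                 "q_value", "direction", "is_de"],
    )
    det.index = pd.Index([f"p{i}" for i in range(len(rows))],
                         name="feature_id")
    return det


class TestProbeCollapsing:
    def _row(self, q, diff):
        direction = "up" if diff > 0 else "down"
        return [0, 0, diff, 0, 4, q / 2, q, direction, q < 0.05]

    def test_one_probe_per_gene_is_identity_with_renaming(self):
        det = _probe_table([self._row(0.01, 1.0), self._row(0.2, -1.0)])
        pm = pd.DataFrame({"probe_id": ["p0", "p1"], "gene_id": ["gA", "gB"]})
        out = collapse_probes_to_genes(det, pm)
        assert list(out.index) == ["gA", "gB"]
        assert out.loc["gA", "q_value"] == 0.01
        assert not out["ambiguous"].any()

    def test_min_q_probe_represents_gene(self):
        det = _probe_table([self._row(0.01, 1.0), self._row(0.2, -1.0)])
        pm = pd.DataFrame({"probe_id": ["p0", "p1"], "gene_id": ["gA", "gA"]})
        out = collapse_probes_to_genes(det, pm)
        assert out.loc["gA", "q_value"] == 0.01
        assert out.loc["gA", "direction"] == "up"
        assert not out.loc["gA", "ambiguous"]

    def test_sign_conflicting_significant_probes_marked_ambiguous(self):
        det = _probe_table([self._row(0.01, 1.0), self._row(0.02, -1.0)])
        pm = pd.DataFrame({"probe_id": ["p0", "p1"], "gene_id": ["gA", "gA"]})
        out = collapse_probes_to_genes(det, pm)
        assert out.loc["gA", "ambiguous"]
        called = call_de(out, 0.05)
        assert up_genes(called) == set() and down_genes(called) == set()

    def test_q_tie_broken_by_p_then_probe_id(self):
        det = _probe_table([self._row(0.01, 1.0), self._row(0.01, -2.0)])
        det.loc["p0", "p_value"] = 0.004
        det.loc["p1", "p_value"] = 0.005
        # p1 is significant too, so the gene is ambiguous, but the
        # representative statistics come from p0 (smaller p)
        pm = pd.DataFrame({"probe_id": ["p0", "p1"], "gene_id": ["gA", "gA"]})
        out = collapse_probes_to_genes(det, pm)
        assert out.loc["gA", "probe_id"] == "p0"

    def test_unmapped_probes_dropped_with_count(self):
        det = _probe_table([self._row(0.01, 1.0), self._row(0.2, -1.0)])
        pm = pd.DataFrame({"probe_id": ["p0"], "gene_id": ["gA"]})
        out = collapse_probes_to_genes(det, pm)
        assert list(out.index) == ["gA"]
        assert out.attrs["n_unmapped_probes"] == 1

    def test_empty_map_is_error(self):
        det = _probe_table([self._row(0.01, 1.0)])
        with pytest.raises(ValidationError, match="empty"):
            collapse_probes_to_genes(det, pd.DataFrame(columns=["probe_id",
                                                                "gene_id"]))


class TestDifferentialExpressionStage:
    def test_group_a_defaults_to_first_seen_and_diff_sign(self, small_expr):
        det = de_statistics(small_expr)
        assert det.attrs["group_a"] == "A"
        assert det.loc["g1", "diff"] > 0 and det.loc["g1", "direction"] == "up"
        assert det.loc["g3", "direction"] == "down"

    def test_linear_input_is_logged_before_testing(self, small_expr):
        linear = ExpressionTable(2.0 ** small_expr.values,
                                 small_expr.groups.copy(), scale="linear")
        det_lin = differential_expression(linear, normalize=False)
        det_log = differential_expression(small_expr, normalize=False)
        np.testing.assert_allclose(det_lin["t_stat"], det_log["t_stat"],
                                   rtol=1e-10)

    def test_more_than_two_groups_rejected(self):
        with pytest.raises(ValidationError, match="two sample groups"):
            de_statistics(_table(np.zeros((2, 6)),
                                 groups=["A", "A", "B", "B", "C", "C"]))
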