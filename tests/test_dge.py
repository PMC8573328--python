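import numpy as np
import pandas as pd
import pytest

from invgsea import ExpressionMatrix, read_expression, SimDesign
from invgsea import simulate_two_contrast_counts
from invgsea.dge import (
    RankedList,
    classify_calls,
    differential_expression,
    rank_genes,
    read_rnk,
    write_rnk,
)
from invgsea.expression import ParseError

from conftest import two_group_matrix


def make_expr(values: dict[str, list[float]], groups: dict[str, str]) -> ExpressionMatrix:
    return ExpressionMatrix(pd.DataFrame(values).T, groups)


class TestReadExpression:
    def _write(self, tmp_path, counts_text, groups_text):
        c = tmp_path / "counts.tsv"
        g = tmp_path / "groups.tsv"
        c.write_text(counts_text)
        g.write_text(groups_text)
        return c, g

    def test_toy_matrix(self, tmp_path):
        c, g = self._write(
            tmp_path,
            "gene\ts1\ts2\ts3\ts4\nActb\t1\t2\t3\t4\nGapdh\t5\t6\t7\t8\nTlr4\t0\t0\t1\t1\n",
            "sample\tgroup\ns1\tctrl\ns2\tctrl\ns3\ttrt\ns4\ttrt\n",
        )
        m = read_expression(c, g)
        assert m.values.shape == (3, 4)
        assert list(m.genes) == ["ACTB", "GAPDH", "TLR4"]  # canonicalized
        assert m.group_samples("ctrl") == ["s1", "s2"]

    def test_duplicate_gene_rows_are_summed(self, tmp_path):
        c, g = self._write(
            tmp_path,
            "gene\ts1\ts2\nACTB\t1\t2\nactb \t10\t20\n",
            "sample\tgroup\ns1\ta\ns2\tb\n",
        )
        m = read_expression(c, g)
        assert m.values.shape == (1, 2)
        assert m.values.loc["ACTB"].tolist() == [11, 22]

    def test_group_map_with_absent_sample_rejected(self, tmp_path):
        c, g = self._write(
            tmp_path,
            "gene\ts1\ts2\nACTB\t1\t2\n",
            "sample\tgroup\ns1\ta\nsX\tb\n",
        )
        with pytest.raises(ParseError, match="sX"):
            read_expression(c, g)

    def test_non_numeric_cell_names_file_and_line(self, tmp_path):
        c, g = self._write(
            tmp_path,
            "gene\ts1\ts2\nACTB\t1\t2\nBAD\tx\t3\n",
            "sample\tgroup\ns1\ta\ns2\tb\n",
        )
        with pytest.raises(ParseError, match=r"counts\.tsv.*line 3"):
            read_expression(c, g)

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            make_expr({"g1": [-1, 2]}, {0: "a", 1: "b"})


class TestDifferentialExpression:
    def test_identical_groups_all_ns(self):
        rng = np.random.default_rng(0)
        vals = rng.poisson(50, size=(20, 3))
        df = pd.DataFrame(
            np.hstack([vals, vals]),
            index=[f"g{i}" for i in range(20)],
            columns=[f"t{i}" for i in range(3)] + [f"c{i}" for i in range(3)],
        )
        expr = ExpressionMatrix(df, {f"t{i}": "t" for i in range(3)} | {f"c{i}": "c" for i in range(3)})
        res = differential_expression(expr, "t", "c")
        assert res.n_up == res.n_down == 0
        assert (res.table["call"] == "ns").all()

    @pytest.mark.parametrize(
        "p,lfc,expected",
        [
            (0.005, 0.25, "up"),
            (0.005, 0.15, "ns"),
            (0.005, -0.25, "down"),
            (0.02, 0.5, "ns"),
            (0.01, 0.25, "ns"),   # threshold is strict: P < 0.01
            (0.005, 0.2, "ns"),   # |log2FC| must exceed 0.2
        ],
    )
    def test_call_rule(self, p, lfc, expected):
        assert classify_calls(np.array([lfc]), np.array([p]))[0] == expected

    @pytest.mark.parametrize("test", ["welch", "moderated"])
    def test_zero_variance_equal_means_p_is_one(self, test):
        df = pd.DataFrame(
            {"s1": [5, 3], "s2": [5, 9], "s3": [5, 2], "s4": [5, 8]},
            index=["const", "vary"],
        )
        expr = ExpressionMatrix(df, {"s1": "t", "s2": "t", "s3": "c", "s4": "c"})
        res = differential_expression(expr, "t", "c", test=test)
        assert res.table.loc["CONST", "p"] == pytest.approx(1.0)

    def test_small_groups_rejected(self):
        expr = make_expr({"g": [1, 2]}, {0: "t", 1: "c"})
        with pytest.raises(ValueError, match=">= 2"):
            differential_expression(expr, "t", "c")

    def test_unknown_test_rejected(self, standard_contrast):
        _, expr_a, _, _ = standard_contrast
        with pytest.raises(ValueError, match="welch"):
            differential_expression(expr_a, "trt", "ctrl", test="bogus")

    def test_sample_order_invariance(self, standard_contrast):
        _, expr_a, _, _ = standard_contrast
        res = differential_expression(expr_a, "trt", "ctrl")
        shuffled_cols = list(np.random.default_rng(5).permutation(expr_a.samples))
        expr_shuf = ExpressionMatrix(
            expr_a.values[shuffled_cols], dict(expr_a.group_map)
        )
        res_shuf = differential_expression(expr_shuf, "trt", "ctrl")
        pd.testing.assert_frame_equal(res.table, res_shuf.table)

    def test_null_p_values_calibrated(self):
        # global null: fraction with p < 0.01 within binomial noise of 0.01
        d = SimDesign(n_genes=2000, n_de=0, n_samples_per_group=6, seed=11)
        counts, _, _ = simulate_two_contrast_counts(d)
        res = differential_expression(two_group_matrix(counts), "trt", "ctrl")
        frac = (res.table["p"] < 0.01).mean()
        margin = 3 * np.sqrt(0.01 * 0.99 / 2000)
        assert abs(frac - 0.01) < margin

    def test_bh_adjustment_monotone_in_p(self, standard_contrast):
        _, expr_a, _, _ = standard_contrast
        t = differential_expression(expr_a, "trt", "ctrl").table.sort_values("p")
        assert (np.diff(t["padj"].to_numpy()) > -1e-12).all()
        assert (t["padj"] >= t["p"] - 1e-12).all()


class TestRankGenes:
    def test_signal_to_noise_with_floored_sd(self):
        # log2(x+1) means 1 vs 0, zero sds floored at 0.2 -> (1-0)/0.4 = 2.5
        df = pd.DataFrame({"t1": [1], "t2": [1], "c1": [0], "c2": [0]}, index=["g"])
        expr = ExpressionMatrix(df, {"t1": "t", "t2": "t", "c1": "c", "c2": "c"})
        ranked = rank_genes(expr, "t", "c", metric="signal_to_noise")
        assert ranked.scores[0] == pytest.approx(2.5)

    def test_log2fc_metric_closed_form(self):
        df = pd.DataFrame({"t1": [4], "t2": [4], "c1": [1], "c2": [1]}, index=["g"])
        expr = ExpressionMatrix(df, {"t1": "t", "t2": "t", "c1": "c", "c2": "c"})
        ranked = rank_genes(expr, "t", "c", metric="log2fc")
        assert ranked.scores[0] == pytest.approx(np.log2(5 / 2))

    def test_identical_groups_rank_lexicographically(self):
        df = pd.DataFrame(
            {"t1": [3, 1, 2], "t2": [3, 1, 2], "c1": [3, 1, 2], "c2": [3, 1, 2]},
            index=["zz", "mm", "aa"],
        )
        expr = ExpressionMatrix(df, {"t1": "t", "t2": "t", "c1": "c", "c2": "c"})
        ranked = rank_genes(expr, "t", "c")
        assert (ranked.scores == 0).all()
        assert list(ranked.genes) == ["AA", "MM", "ZZ"]

    def test_unknown_metric_lists_valid_ones(self, standard_contrast):
        _, expr_a, _, _ = standard_contrast
        with pytest.raises(ValueError, match="signal_to_noise"):
            rank_genes(expr_a, "trt", "ctrl", metric="bogus")

    def test_up_calls_have_positive_metric(self, standard_contrast):
        _, expr_a, _, _ = standard_contrast
        res = differential_expression(expr_a, "trt", "ctrl")
        ranked = rank_genes(expr_a, "trt", "ctrl")
        r = ranked.as_series()
        assert (r[list(res.genes_called("up"))] > 0).all()
        assert (r[list(res.genes_called("down"))] < 0).all()

    def test_rnk_round_trip(self, tmp_path, standard_contrast):
        _, expr_a, _, _ = standard_contrast
        ranked = rank_genes(expr_a, "trt", "ctrl")
        path = tmp_path / "a.rnk"
        write_rnk(ranked, path)
        back = read_rnk(path)
        assert list(back.genes) == list(ranked.genes)
        np.testing.assert_allclose(back.scores, ranked.scores, rtol=1e-4)


class TestRankedList:
    def test_duplicate_genes_rejected(self):
        with pytest.raises(ValueError):
            RankedList(np.array(["a", "a"]), np.array([1.0, 0.5]))

    def test_nonfinite_scores_rejected(self):
        with pytest.raises(ValueError):
            RankedList(np.array(["a", "b"]), np.array([1.0, np.inf]))
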