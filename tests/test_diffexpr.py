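"""Probe summarization, two-group tests, BH adjustment, DE calls."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirrescue import (ContrastResult, bh_adjust, call_de, contrast,
                       summarize_probes)
from mirrescue.containers import ExpressionMatrix
from mirrescue.diffexpr import squeeze_variances


def _expr(values, conditions, probe_gene):
    return ExpressionMatrix(
        values=values,
        conditions=pd.Series(conditions),
        probe_gene=pd.Series(probe_gene),
    )


class TestSummarizeProbes:
    def test_single_probe_gene_is_identity_and_pair_is_midpoint(self):
        values = pd.DataFrame(
            {"s1": [2.0 ** 5, 2.0 ** 6, 2.0 ** 8]},
            index=["p1", "p2", "p3"])
        m = _expr(values, {"s1": "control"},
                  {"p1": "gA", "p2": "gB", "p3": "gB"})
        gene = summarize_probes(m)
        assert gene.loc["gA", "s1"] == pytest.approx(5.0)
        assert gene.loc["gB", "s1"] == pytest.approx(7.0)  # (6 + 8) / 2

    def test_probe_partition_is_conserved(self, small_cohort):
        expr, _ = small_cohort
        assert expr.probe_gene.groupby(expr.probe_gene).size().sum() \
            == expr.values.shape[0]
        gene = summarize_probes(expr)
        assert set(gene.index) == set(expr.probe_gene.unique())


class TestContrast:
    def _matrix(self, a_vals, b_vals):
        n = len(a_vals[0])
        cols = [f"a{i}" for i in range(len(a_vals))] + \
               [f"b{i}" for i in range(len(b_vals))]
        data = np.column_stack([*a_vals, *b_vals])
        return pd.DataFrame(data, columns=cols,
                            index=[f"g{i}" for i in range(n)]), \
            [f"a{i}" for i in range(len(a_vals))], \
            [f"b{i}" for i in range(len(b_vals))]

    def test_identical_groups_have_zero_logfc(self):
        v = np.array([4.0, 5.0, 6.0])
        m, a, b = self._matrix([v, v + 0.1], [v, v + 0.1])
        res = contrast(m, a, b)
        assert np.allclose(res.table["log2fc"], 0.0)

    def test_zero_variance_hand_example(self):
        m, a, b = self._matrix([[4.0], [4.0]], [[6.0], [6.0]])
        res = contrast(m, a, b)
        assert res.table["log2fc"].iloc[0] == pytest.approx(2.0)
        assert res.table["fc"].iloc[0] == pytest.approx(4.0)
        assert res.table["p"].iloc[0] == 0.0  # degenerate: delta != 0
        m2, a2, b2 = self._matrix([[4.0], [4.0]], [[4.0], [4.0]])
        assert contrast(m2, a2, b2).table["p"].iloc[0] == 1.0

    @pytest.mark.parametrize("method", ["welch", "moderated"])
    def test_group_swap_negates_logfc_keeps_p(self, method):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.normal(8, 1, (40, 6)),
                         columns=list("abcdef"),
                         index=[f"g{i}" for i in range(40)])
        r1 = contrast(m, ["a", "b", "c"], ["d", "e", "f"], method=method)
        r2 = contrast(m, ["d", "e", "f"], ["a", "b", "c"], method=method)
        assert np.allclose(r1.table["log2fc"], -r2.table["log2fc"])
        assert np.allclose(r1.table["p"], r2.table["p"])

    def test_input_validation(self):
        m, a, b = self._matrix([[1.0], [2.0]], [[3.0], [4.0]])
        with pytest.raises(ValueError, match="overlap"):
            contrast(m, a, [a[0], b[0]])
        with pytest.raises(ValueError, match="at least 2"):
            contrast(m, a[:1], b)


class TestModeratedVariance:
    def test_matches_bioconductor_limma(self, tmp_path):
        """Shrunken variances and p-values agree with limma's eBayes."""
        assert shutil.which("Rscript"), "Rscript expected on PATH"
        rng = np.random.default_rng(42)
        mat = rng.normal(8, 1, size=(80, 6)) \
            * np.exp(rng.normal(0, 0.3, size=(80, 1)))
        cols = ["a1", "a2", "a3", "b1", "b2", "b3"]
        df = pd.DataFrame(mat, index=[f"g{i}" for i in range(80)], columns=cols)
        tsv = tmp_path / "m.tsv"
        df.to_csv(tsv, sep="\t")
        script = tmp_path / "check.R"
        script.write_text(f'''
suppressMessages(library(limma))
m <- as.matrix(read.delim("{tsv}", row.names=1))
design <- model.matrix(~ factor(c("a","a","a","b","b","b")))
fit <- eBayes(lmFit(m, design))
res <- data.frame(p=fit$p.value[,2], post=fit$s2.post)
write.table(res, "{tmp_path}/out.tsv", sep="\\t", quote=FALSE)
cat(fit$df.prior, fit$s2.prior, "\\n", file="{tmp_path}/prior.txt")
''')
        subprocess.run(["Rscript", str(script)], check=True,
                       capture_output=True)
        ref = pd.read_csv(tmp_path / "out.tsv", sep="\t")
        d0_ref, s0_ref = map(float, (tmp_path / "prior.txt").read_text().split())

        res = contrast(df, cols[:3], cols[3:], method="moderated")
        s2 = (df[cols[:3]].var(axis=1) * 2 + df[cols[3:]].var(axis=1) * 2) / 4
        post, d0, s0 = squeeze_variances(s2.to_numpy(), 4)
        assert d0 == pytest.approx(d0_ref, rel=1e-5)
        assert s0 == pytest.approx(s0_ref, rel=1e-5)
        assert np.allclose(post, ref["post"], rtol=1e-8)
        assert np.allclose(res.table["p"], ref["p"], rtol=1e-8, atol=1e-12)


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_boundaries(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)
        assert bh_adjust([]).size == 0

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    def test_monotone_and_matches_statsmodels(self, pvals):
        from statsmodels.stats.multitest import multipletests
        q = bh_adjust(pvals)
        p = np.asarray(pvals)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)  # monotone in p
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, ref, atol=1e-12)


class TestCallDe:
    def _result(self, rows):
        table = pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))],
                             columns=["log2fc", "p", "q"])
        table["fc"] = np.exp2(table["log2fc"])
        table["de"] = False
        return ContrastResult(table=table, group_a="A", group_b="B",
                              method="welch", fc_threshold=1.3,
                              p_threshold=0.05, q_threshold=0.05)

    def test_fc_inequality_is_strict(self):
        res = self._result([[np.log2(1.3), 1e-6, 1e-6]])
        assert call_de(res) == set()

    def test_all_thresholds_met(self):
        res = self._result([[1.0, 0.001, 0.04]])
        assert call_de(res) == {"g0"}

    def test_empty_result(self):
        res = self._result([])
        assert call_de(res) == set()

    def test_downregulation_is_symmetric(self):
        res = self._result([[-1.0, 0.001, 0.01]])
        assert call_de(res) == {"g0"}
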