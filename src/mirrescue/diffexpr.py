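"""Two-group differential expression on log2 intensities.

Pipeline: probe -> gene summarization (mean of log2 probe intensities), a
per-gene two-sample test (Welch t by default; an empirical-Bayes
moderated-variance t, limma-style, as an option for small replicate counts),
Benjamini-Hochberg step-up adjustment, and a three-way call:

    DE  <=>  2^|log2FC| > fc_threshold  AND  p < p_threshold  AND  q < q_threshold

The fold-change rule is symmetric (two-sided on the linear scale) and all
three inequalities are strict.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Set

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import ExpressionMatrix


def summarize_probes(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Gene-level log2 matrix: per sample, mean of the gene's probes' log2."""
    if len(matrix.probe_gene) == 0:
        raise ValueError("empty probe->gene map")
    log2 = matrix.log2()
    gene_log2 = log2.groupby(matrix.probe_gene).mean()
    gene_log2.index.name = "gene"
    return gene_log2


@dataclass
class ContrastResult:
    """Per-gene statistics for one two-group comparison (B vs A).

    ``table`` columns: log2fc (mean_B - mean_A of log2 values), fc = 2^log2fc,
    p, q (BH-adjusted), de.
    """

    table: pd.DataFrame
    group_a: str
    group_b: str
    method: str
    fc_threshold: float
    p_threshold: float
    q_threshold: float

    def de_set(self) -> Set[str]:
        return set(self.table.index[self.table["de"]])

    def write(self, path) -> None:
        self.table.rename_axis("gene").to_csv(path, sep="\t", float_format="%.6g")


def _welch(a: np.ndarray, b: np.ndarray):
    res = stats.ttest_ind(b, a, axis=1, equal_var=False)
    return np.asarray(res.pvalue)


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x
    for _ in range(60):
        tri = special.polygamma(1, y)
        step = (tri - x) / special.polygamma(2, y)
        y_new = y - step
        y_new = np.maximum(y_new, 1e-8)
        if np.all(np.abs(y_new - y) < 1e-10 * np.maximum(y, 1.0)):
            y = y_new
            break
        y = y_new
    return y


def squeeze_variances(s2: np.ndarray, df: float):
    """Empirical-Bayes shrinkage of per-gene variances toward a fitted prior.

    Fits a scaled inverse-chi-square prior (d0, s0^2) to the observed sample
    variances by matching the moments of log(s^2), then returns the posterior
    variances (d0*s0^2 + df*s2) / (d0 + df) together with (d0, s0^2).
    d0 = inf means the variances carry no excess dispersion beyond chi-square
    sampling noise and collapse onto s0^2.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need at least two positive variances to fit a prior")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    excess = z.var(ddof=1) - special.polygamma(1, df / 2.0)
    if excess <= 0:
        d0 = np.inf
        s0_2 = float(np.exp(e_mean))
        post = np.full_like(s2, s0_2)
    else:
        d0 = float(2.0 * _trigamma_inverse(np.array([excess]))[0])
        s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        post = (d0 * s0_2 + df * s2) / (d0 + df)
    return post, d0, s0_2


def _moderated(a: np.ndarray, b: np.ndarray):
    na, nb = a.shape[1], b.shape[1]
    df = na + nb - 2
    ss = a.var(axis=1, ddof=1) * (na - 1) + b.var(axis=1, ddof=1) * (nb - 1)
    s2 = ss / df
    post, d0, _ = squeeze_variances(s2, df)
    delta = b.mean(axis=1) - a.mean(axis=1)
    se = np.sqrt(post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / se
    total_df = df + d0
    if np.isinf(total_df):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), total_df)
    return np.asarray(p)


def contrast(gene_matrix: pd.DataFrame, group_a: Sequence[str],
             group_b: Sequence[str], *, method: str = "welch",
             fc_threshold: float = 1.3, p_threshold: float = 0.05,
             q_threshold: float = 0.05,
             label_a: str = "A", label_b: str = "B") -> ContrastResult:
    """Per-gene two-group comparison on a gene x sample log2 matrix.

    Welch's unequal-variance t-test is the default; ``method="moderated"``
    uses the empirical-Bayes shrunken-variance t instead.  Genes whose two
    groups both have zero variance get p = 0 when the means differ and p = 1
    when they agree (degenerate-input totality).
    """
    group_a, group_b = list(group_a), list(group_b)
    if min(len(group_a), len(group_b)) < 2:
        raise ValueError("each group needs at least 2 samples")
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    for t in (fc_threshold, p_threshold, q_threshold):
        if t <= 0:
            raise ValueError("thresholds must be positive")
    missing = (set(group_a) | set(group_b)) - set(gene_matrix.columns)
    if missing:
        raise ValueError(f"samples not in matrix: {sorted(missing)}")

    a = gene_matrix[group_a].to_numpy(float)
    b = gene_matrix[group_b].to_numpy(float)
    delta = b.mean(axis=1) - a.mean(axis=1)

    if method == "welch":
        with np.errstate(divide="ignore", invalid="ignore"):
            p = _welch(a, b)
    elif method == "moderated":
        p = _moderated(a, b)
    else:
        raise ValueError(f"unknown method {method!r}")

    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    p = np.where(degenerate, np.where(delta != 0, 0.0, 1.0), p)
    p = np.nan_to_num(p, nan=1.0)

    q = bh_adjust(p)
    de = (np.exp2(np.abs(delta)) > fc_threshold) & (p < p_threshold) \
        & (q < q_threshold)
    table = pd.DataFrame({
        "log2fc": delta,
        "fc": np.exp2(delta),
        "p": p,
        "q": q,
        "de": de,
    }, index=gene_matrix.index)
    return ContrastResult(table=table, group_a=label_a, group_b=label_b,
                          method=method, fc_threshold=fc_threshold,
                          p_threshold=p_threshold, q_threshold=q_threshold)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Sort ascending, set q_(i) = min_{j>=i} p_(j) * m / j, restore the input
    order, clamp to <= 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_de(result: ContrastResult, fc_threshold: float = 1.3,
            p_threshold: float = 0.05, q_threshold: float = 0.05) -> Set[str]:
    """Gene ids with 2^|log2FC| > fc AND p < p_thr AND q < q_thr (all strict)."""
    for t in (fc_threshold, p_threshold, q_threshold):
        if t <= 0:
            raise ValueError("thresholds must be positive")
    t = result.table
    keep = (np.exp2(np.abs(t["log2fc"])) > fc_threshold) \
        & (t["p"] < p_threshold) & (t["q"] < q_threshold)
    return set(t.index[keep])
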