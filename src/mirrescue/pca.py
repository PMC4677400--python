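"""PCA of log2 expression (samples = observations, probes = variables) and
selection of the probes carrying the most PC weight.

The decomposition is a plain SVD of the probe-centered data (covariance PCA,
no per-probe scaling); variance fractions are sigma_k^2 / sum(sigma^2) in
percent, and loadings have unit Euclidean norm per component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd


@dataclass
class PcaResult:
    scores: pd.DataFrame        # samples x components
    loadings: pd.DataFrame      # probes x components, unit-norm columns
    variance_pct: pd.Series     # percent of total variance per component

    @property
    def components(self) -> List[str]:
        return list(self.scores.columns)


def pca(log2_matrix: pd.DataFrame) -> PcaResult:
    """SVD-based PCA of a probes x samples log2 matrix.

    Probes are centered across samples; components are ordered by decreasing
    variance.
    """
    if log2_matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    X = log2_matrix.to_numpy(float).T          # samples x probes
    if np.unique(X, axis=0).shape[0] < 2:
        raise ValueError("need at least 2 distinct samples")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    names = [f"PC{i + 1}" for i in range(s.size)]
    total = float((s ** 2).sum())
    scores = pd.DataFrame(U * s, index=log2_matrix.columns, columns=names)
    loadings = pd.DataFrame(Vt.T, index=log2_matrix.index, columns=names)
    variance_pct = pd.Series(100.0 * s ** 2 / total, index=names,
                             name="variance_pct")
    return PcaResult(scores=scores, loadings=loadings, variance_pct=variance_pct)


@dataclass
class ProbeSelection:
    probes: List[str]
    component: str
    quantile: float
    weight_fraction: float      # sum |loading| selected / sum |loading| all
    n_unique_genes: Optional[int] = None


def select_top_loadings(result: PcaResult, component: int = 1,
                        quantile: float = 0.10,
                        probe_gene: Optional[pd.Series] = None
                        ) -> ProbeSelection:
    """Top ``ceil(quantile * n_probes)`` probes by |loading| on one component.

    Ties in |loading| break on probe id for determinism.  The weight fraction
    is the share of total absolute loading carried by the selection; the
    unique gene count is reported when a probe->gene map is given.
    """
    if not 0.0 < quantile <= 1.0:
        raise ValueError("quantile must lie in (0, 1]")
    name = f"PC{component}"
    if name not in result.loadings.columns:
        raise ValueError(f"component {name} not present")
    absload = result.loadings[name].abs()
    n_sel = math.ceil(quantile * len(absload))
    # descending |loading|, exact ties broken by probe id
    order = np.lexsort((absload.index.to_numpy(), -absload.to_numpy()))
    selected = list(absload.index[order[:n_sel]])
    weight_fraction = float(absload.loc[selected].sum() / absload.sum())
    n_unique = None
    if probe_gene is not None:
        n_unique = int(probe_gene.loc[selected].nunique())
    return ProbeSelection(probes=selected, component=name, quantile=quantile,
                          weight_fraction=weight_fraction,
                          n_unique_genes=n_unique)
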