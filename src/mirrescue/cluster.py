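"""Sample clustering with multiscale-bootstrap clade support.

The dendrogram is built by deterministic agglomerative clustering on a sample
distance matrix (1 - Pearson correlation of log2 probe vectors by default).
Clade support follows the multiscale bootstrap recipe: probes (features) are
resampled with replacement at several relative sizes r, the tree is rebuilt
for every resample, and per observed clade the bootstrap proportion BP_r is
recorded.  A weighted probit regression of z_r = Phi^-1(1 - BP_r) on
v*sqrt(r) + c/sqrt(r) yields the approximately unbiased support
AU = 100 * (1 - Phi(v - c)); BP is reported at r = 1.  Both live on a 0-100
scale.

The resampling loop never rebuilds the probe matrix: a bootstrap draw is an
integer weight vector over probes, so the weighted sample-by-sample Gram
matrix (and hence every pairwise correlation) comes from one matrix product
per batch of resamples.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

DEFAULT_SCALES = tuple(round(0.5 + 0.1 * i, 1) for i in range(10))


def sample_distance(log2_matrix: pd.DataFrame, metric: str = "correlation"
                    ) -> pd.DataFrame:
    """Pairwise sample distances over probes (columns = samples).

    ``correlation``: d(s,t) = 1 - Pearson r of the two log2 probe vectors;
    ``euclidean``: plain Euclidean distance.  Symmetric with a zero diagonal.
    """
    if log2_matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    X = log2_matrix.to_numpy(float).T  # samples x probes
    if metric == "correlation":
        sd = X.std(axis=1)
        if np.any(sd == 0):
            bad = [log2_matrix.columns[i] for i in np.flatnonzero(sd == 0)]
            raise ValueError(f"constant sample vector(s) under correlation "
                             f"metric: {bad}")
        d = 1.0 - np.corrcoef(X)
    elif metric == "euclidean":
        diff = X[:, None, :] - X[None, :, :]
        d = np.sqrt((diff ** 2).sum(axis=2))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return pd.DataFrame(d, index=log2_matrix.columns, columns=log2_matrix.columns)


# ---------------------------------------------------------------------------
# deterministic agglomerative clustering (small sample counts)
# ---------------------------------------------------------------------------

def _merge_masks(d: np.ndarray, method: str) -> Tuple[list, list]:
    """Agglomerate an n x n distance matrix; returns (merges, clade masks).

    merges: (node_left, node_right, height) with scipy-style node ids (leaves
    0..n-1, the k-th internal node n+k).  Clades are bitmasks over leaves.
    Exact distance ties break on the lexicographically smallest sorted member
    tuple of the would-be clade.
    """
    n = d.shape[0]
    work = d.astype(float).copy()
    np.fill_diagonal(work, np.inf)
    alive = np.ones(n, dtype=bool)
    masks = [1 << i for i in range(n)]
    sizes = np.ones(n)
    node_id = list(range(n))
    merges: list = []
    out_masks: list = []

    def members(slot: int) -> tuple:
        m, out = masks[slot], []
        while m:
            low = m & -m
            out.append(low.bit_length() - 1)
            m ^= low
        return tuple(out)

    for step in range(n - 1):
        flat = np.argmin(work)
        i, j = divmod(int(flat), n)
        dmin = work[i, j]
        ties = np.argwhere(work == dmin)
        if len(ties) > 2:  # symmetric matrix: a unique pair appears twice
            best = None
            for a, b in ties:
                if a >= b:
                    continue
                key = tuple(sorted(members(int(a)) + members(int(b))))
                if best is None or key < best[0]:
                    best = (key, int(a), int(b))
            i, j = best[1], best[2]
        else:
            i, j = min(i, j), max(i, j)

        # Lance-Williams update into slot i
        if method == "average":
            new_row = (sizes[i] * work[i] + sizes[j] * work[j]) / (sizes[i] + sizes[j])
        elif method == "complete":
            new_row = np.maximum(work[i], work[j])
        elif method == "single":
            new_row = np.minimum(work[i], work[j])
        else:
            raise ValueError(f"unknown linkage {method!r}")
        merges.append((node_id[i], node_id[j], float(dmin)))
        masks[i] |= masks[j]
        out_masks.append(masks[i])
        sizes[i] += sizes[j]
        node_id[i] = n + step
        work[i, :] = new_row
        work[:, i] = new_row
        work[i, i] = np.inf
        work[j, :] = np.inf
        work[:, j] = np.inf
        alive[j] = False
    return merges, out_masks


@dataclass
class Clade:
    members: frozenset
    height: float
    bp: Optional[float] = None          # 0-100, at scale r = 1
    au: Optional[float] = None          # 0-100
    degenerate_fit: bool = False


@dataclass
class Dendrogram:
    """Binary merge tree over samples, optionally annotated with AU/BP."""

    labels: List[str]
    merges: List[Tuple[int, int, float]]
    clades: List[Clade] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.clades:
            n = len(self.labels)
            masks = {}
            for k, (a, b, h) in enumerate(self.merges):
                mask = self._node_mask(a, masks) | self._node_mask(b, masks)
                masks[n + k] = mask
                self.clades.append(Clade(
                    members=frozenset(self.labels[i] for i in self._bits(mask)),
                    height=h))

    def _node_mask(self, node: int, masks: dict) -> int:
        return (1 << node) if node < len(self.labels) else masks[node]

    @staticmethod
    def _bits(mask: int):
        while mask:
            low = mask & -mask
            yield low.bit_length() - 1
            mask ^= low

    def find(self, members) -> Optional[Clade]:
        target = frozenset(members)
        for clade in self.clades:
            if clade.members == target:
                return clade
        return None

    def to_newick(self) -> str:
        """Newick string with internal labels ``AU|BP`` (rounded to 0.1)."""
        n = len(self.labels)
        nodes: Dict[int, str] = {i: self.labels[i] for i in range(n)}
        heights = {i: 0.0 for i in range(n)}
        for k, (a, b, h) in enumerate(self.merges):
            clade = self.clades[k]
            label = ""
            if clade.au is not None or clade.bp is not None:
                au = "" if clade.au is None else f"{clade.au:.1f}"
                bp = "" if clade.bp is None else f"{clade.bp:.1f}"
                label = f"{au}|{bp}"
            bl_a = max(h - heights[a], 0.0)
            bl_b = max(h - heights[b], 0.0)
            nodes[n + k] = f"({nodes[a]}:{bl_a:.6g},{nodes[b]}:{bl_b:.6g}){label}"
            heights[n + k] = h
        return nodes[n + len(self.merges) - 1] + ";"


def hierarchical_cluster(distance: pd.DataFrame, linkage: str = "average"
                         ) -> Dendrogram:
    """Agglomerative merge tree with deterministic tie-breaking."""
    d = distance.to_numpy(float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    if np.any(np.diag(d) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    merges, _ = _merge_masks(d, linkage)
    return Dendrogram(labels=list(distance.index), merges=merges)


# ---------------------------------------------------------------------------
# multiscale bootstrap
# ---------------------------------------------------------------------------

def _fit_au(bp: np.ndarray, scales: np.ndarray, n_boot: int
            ) -> Tuple[float, bool]:
    """AU from per-scale bootstrap proportions via weighted probit regression.

    Degenerate cases: a clade present in every resample at every scale has
    AU = 100; one never observed anywhere has AU = 0 and is flagged.
    """
    bp = np.asarray(bp, dtype=float)
    if np.all(bp >= 1.0):
        return 100.0, False
    if np.all(bp <= 0.0):
        return 0.0, True
    eps = 1.0 / (2.0 * n_boot)
    bpc = np.clip(bp, eps, 1.0 - eps)
    z = norm.ppf(1.0 - bpc)
    x = np.sqrt(scales)
    design = np.column_stack([x, 1.0 / x])
    w = n_boot * norm.pdf(z) ** 2 / (bpc * (1.0 - bpc))
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(design * sw[:, None], z * sw, rcond=None)
    v, c = coef
    return float(100.0 * (1.0 - norm.cdf(v - c))), False


def au_bootstrap(log2_matrix: pd.DataFrame, n_boot: int = 1000,
                 scales: Sequence[float] = DEFAULT_SCALES,
                 seed: Optional[int] = None, metric: str = "correlation",
                 linkage: str = "average") -> Dendrogram:
    """Observed dendrogram annotated with AU and BP clade support.

    Resamples probes (rows) with replacement at each relative size in
    ``scales`` (``n_boot`` times each), reclusters, and fits the multiscale
    probit model per observed clade.
    """
    if log2_matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if len(scales) < 2:
        raise ValueError("need at least 2 scales")
    scales = np.asarray(sorted(scales), dtype=float)

    observed_d = sample_distance(log2_matrix, metric=metric)
    tree = hierarchical_cluster(observed_d, linkage=linkage)
    _, observed_masks = _merge_masks(observed_d.to_numpy(float), linkage)

    X = log2_matrix.to_numpy(float).T  # S x P
    S, P = X.shape
    rng = np.random.default_rng(seed)
    iu0, iu1 = np.triu_indices(S)
    if metric == "correlation":
        Y = (X[iu0] * X[iu1]).T                    # P x n_pairs (incl. diagonal)
    else:
        lo0, lo1 = np.triu_indices(S, k=1)
        Y = ((X[lo0] - X[lo1]) ** 2).T             # P x n_offdiag

    chunk = max(1, int(4_000_000 // max(P, 1)))
    bp_per_scale = np.zeros((len(observed_masks), len(scales)))

    for si, r in enumerate(scales):
        m = max(2, int(round(r * P)))
        counts: Counter = Counter()
        done = 0
        while done < n_boot:
            bs = min(chunk, n_boot - done)
            idx = rng.integers(0, P, size=(bs, m))
            shift = (np.arange(bs) * P)[:, None]
            W = np.bincount((idx + shift).ravel(), minlength=bs * P) \
                .reshape(bs, P).astype(float)
            dist_stack = _weighted_distances(W, X, Y, iu0, iu1, m, metric)
            for b in range(bs):
                _, masks = _merge_masks(dist_stack[b], linkage)
                for mask in masks:
                    counts[mask] += 1
            done += bs
        for ci, mask in enumerate(observed_masks):
            bp_per_scale[ci, si] = counts.get(mask, 0) / n_boot

    r1 = int(np.argmin(np.abs(scales - 1.0)))
    for ci, clade in enumerate(tree.clades):
        au, degenerate = _fit_au(bp_per_scale[ci], scales, n_boot)
        clade.au = au
        clade.bp = float(100.0 * bp_per_scale[ci, r1])
        clade.degenerate_fit = degenerate
    return tree


def _weighted_distances(W: np.ndarray, X: np.ndarray, Y: np.ndarray,
                        iu0: np.ndarray, iu1: np.ndarray, m: int,
                        metric: str) -> np.ndarray:
    """Distance matrices for a batch of bootstrap weight vectors."""
    B, S = W.shape[0], X.shape[0]
    if metric == "correlation":
        Q = (W @ Y) / m                       # B x n_pairs: E_w[x_s x_t]
        M = (W @ X.T) / m                     # B x S: weighted means
        C = np.empty((B, S, S))
        C[:, iu0, iu1] = Q
        C[:, iu1, iu0] = Q
        cov = C - M[:, :, None] * M[:, None, :]
        var = np.maximum(np.einsum("bss->bs", cov), 1e-300)
        denom = np.sqrt(var[:, :, None] * var[:, None, :])
        d = 1.0 - cov / denom
        d[:, np.arange(S), np.arange(S)] = 0.0
    else:
        lo0, lo1 = np.triu_indices(S, k=1)
        Dsq = W @ Y                           # B x n_offdiag
        d = np.zeros((B, S, S))
        d[:, lo0, lo1] = np.sqrt(np.maximum(Dsq, 0.0))
        d[:, lo1, lo0] = d[:, lo0, lo1]
    return d
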