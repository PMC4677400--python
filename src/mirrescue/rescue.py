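"""Quadrant classification of rescued genes and the rescue summary metrics.

Genes differentially expressed in BOTH comparisons -- perturbed vs control
(x = log2FC) and treated vs perturbed (y = log2FC) -- are placed in
fold-change quadrants.  Labels follow the rescue-experiment convention, which
is mirrored relative to the mathematical one:

    QI   x > 0, y > 0      up under perturbation, further up under treatment
    QII  x > 0, y < 0      up under perturbation, reverted by treatment
    QIII x < 0, y < 0      down, further down
    QIV  x < 0, y > 0      down under perturbation, reverted by treatment

QII and QIV are the inversely modulated ("rescued") quadrants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import ContrastResult


def quadrant_of(x: float, y: float) -> str:
    if x > 0:
        return "QI" if y > 0 else "QII"
    return "QIV" if y > 0 else "QIII"


def build_quadrant_table(contrast1: ContrastResult, contrast2: ContrastResult,
                         de1: Iterable[str], de2: Iterable[str],
                         target_flags: Optional[Iterable[str]] = None
                         ) -> pd.DataFrame:
    """Quadrant table over the intersection of the two DE gene sets.

    ``x`` comes from contrast1 (perturbed vs control), ``y`` from contrast2
    (treated vs perturbed).  ``target_flags`` optionally marks predicted
    miRNA targets.  DE-called genes cannot sit on an axis (the fold-change
    filter excludes log2FC = 0), so every gene gets a quadrant.
    """
    de1, de2 = set(de1), set(de2)
    genes = sorted(de1 & de2)
    missing = [g for g in genes if g not in contrast1.table.index
               or g not in contrast2.table.index]
    if missing:
        raise ValueError(f"{len(missing)} intersected genes missing a fold "
                         f"change (e.g. {missing[:3]})")
    x = contrast1.table.loc[genes, "log2fc"].to_numpy()
    y = contrast2.table.loc[genes, "log2fc"].to_numpy()
    table = pd.DataFrame({
        "x": x,
        "y": y,
        "quadrant": [quadrant_of(a, b) for a, b in zip(x, y)],
    }, index=pd.Index(genes, name="gene"))
    if target_flags is not None:
        flagged = set(target_flags)
        table["is_target"] = [g in flagged for g in genes]
    return table


@dataclass
class RescueMetrics:
    """Summary of how much of the perturbation signature the treatment moves.

    fraction_affected: share of perturbation-altered genes also changed by the
    treatment; fraction_inverse: share of those moved in the opposite
    direction (QII + QIV); pearson_r: correlation of (x, y) over the
    intersection (None when fewer than 2 genes).
    """

    n_altered: int
    n_intersect: int
    fraction_affected: float
    fraction_inverse: float
    quadrant_counts: dict
    pearson_r: Optional[float]
    pearson_p: Optional[float]


def rescue_metrics(table: pd.DataFrame, n_altered: int) -> RescueMetrics:
    """Rescue summary statistics for a quadrant table.

    ``n_altered`` is the size of the perturbed-vs-control DE set the table
    was intersected against; it bounds the table size from above.
    """
    n_intersect = len(table)
    if n_altered < n_intersect:
        raise ValueError("n_altered must be >= table size")
    counts = {q: int((table["quadrant"] == q).sum())
              for q in ("QI", "QII", "QIII", "QIV")}
    fraction_affected = n_intersect / n_altered if n_altered else float("nan")
    fraction_inverse = ((counts["QII"] + counts["QIV"]) / n_intersect
                        if n_intersect else float("nan"))
    if n_intersect >= 2:
        r, p = stats.pearsonr(table["x"], table["y"])
        r, p = float(r), float(p)
    else:
        r = p = None  # correlation undefined
    return RescueMetrics(n_altered=int(n_altered), n_intersect=n_intersect,
                         fraction_affected=fraction_affected,
                         fraction_inverse=fraction_inverse,
                         quadrant_counts=counts, pearson_r=r, pearson_p=p)
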