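"""Reads-per-million normalization and the fold-change/abundance screen.

The screen reproduces a standard small-RNA-seq hit filter: a miRNA is called
when its two-group fold change reaches a ratio threshold (default 1.8, either
direction) AND the more abundant group mean exceeds an rpm floor (default
200).  Group summaries are arithmetic means of per-sample rpm; a small
pseudocount (0.5 rpm) on both sides of the ratio guards zero division.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Sequence

import numpy as np
import pandas as pd

from .containers import MirnaCountMatrix


def normalize_rpm(counts: MirnaCountMatrix) -> pd.DataFrame:
    """Counts scaled to reads per million: count / library_size * 1e6.

    Library sizes default to column sums, in which case every column of the
    result sums to exactly 1e6 (when the column is non-empty).
    """
    lib = counts.effective_library_size()
    if np.any(lib.to_numpy() <= 0):
        empty = lib.index[lib.to_numpy() <= 0].tolist()
        raise ValueError(f"zero library size for samples: {empty}")
    return counts.counts / lib * 1e6


@dataclass
class MirnaScreenResult:
    """Per-miRNA screen table plus the thresholds that produced it."""

    table: pd.DataFrame  # mean_rpm_<a>, mean_rpm_<b>, fc, direction, passed
    group_a: str
    group_b: str
    fc_threshold: float
    rpm_threshold: float
    pseudocount: float

    def pass_set(self) -> set:
        return set(self.table.index[self.table["passed"]])

    def down_set(self) -> set:
        t = self.table
        return set(t.index[t["passed"] & (t["direction"] == "down")])

    def up_set(self) -> set:
        t = self.table
        return set(t.index[t["passed"] & (t["direction"] == "up")])


def screen_mirnas(rpm: pd.DataFrame, groups: Dict[str, Sequence[str]],
                  fc_threshold: float = 1.8, rpm_threshold: float = 200.0,
                  pseudocount: float = 0.5) -> MirnaScreenResult:
    """Two-group fold-change + abundance screen on an rpm matrix.

    ``groups`` maps exactly two group names (reference first by insertion
    order, e.g. {"control": [...], "perturbed": [...]}) to non-empty sample
    lists.  FC = (mean rpm of the second group + pseudocount) / (mean rpm of
    the first + pseudocount); direction is "up" when FC >= fc_threshold,
    "down" when FC <= 1/fc_threshold, "none" otherwise; a hit additionally
    needs max(group means) > rpm_threshold.
    """
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {len(groups)}")
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must be > 1")
    (name_a, samples_a), (name_b, samples_b) = groups.items()
    for name, samples in ((name_a, samples_a), (name_b, samples_b)):
        if len(samples) == 0:
            raise ValueError(f"group {name!r} is empty")
        unknown = set(samples) - set(rpm.columns)
        if unknown:
            raise ValueError(f"unknown samples in group {name!r}: {sorted(unknown)}")

    mean_a = rpm[list(samples_a)].mean(axis=1)
    mean_b = rpm[list(samples_b)].mean(axis=1)
    fc = (mean_b + pseudocount) / (mean_a + pseudocount)
    direction = pd.Series("none", index=rpm.index)
    direction[fc >= fc_threshold] = "up"
    direction[fc <= 1.0 / fc_threshold] = "down"
    abundant = np.maximum(mean_a, mean_b) > rpm_threshold
    passed = (direction != "none") & abundant

    table = pd.DataFrame({
        f"mean_rpm_{name_a}": mean_a,
        f"mean_rpm_{name_b}": mean_b,
        "fc": fc,
        "direction": direction,
        "passed": passed,
    })
    return MirnaScreenResult(table=table, group_a=name_a, group_b=name_b,
                             fc_threshold=fc_threshold,
                             rpm_threshold=rpm_threshold, pseudocount=pseudocount)
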