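"""In-memory containers for the two assay matrices.

Both are thin wrappers around pandas DataFrames: features on the rows, samples
on the columns, plus the per-sample metadata each assay needs (condition
labels and a probe->gene map for the array; library sizes for the small-RNA
counts).  Text round-trip is plain TSV, first column = feature id, header =
sample ids.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd


def _require_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique()[:5].tolist()
        raise ValueError(f"duplicate {what}: {dupes}")


@dataclass
class ExpressionMatrix:
    """Probe-level intensity matrix with condition labels and probe->gene map.

    ``values`` are strictly positive linear-scale intensities (probes x
    samples); log2 is taken downstream.
    """

    values: pd.DataFrame
    conditions: pd.Series  # sample id -> condition label
    probe_gene: pd.Series  # probe id -> gene id

    def __post_init__(self) -> None:
        _require_unique(self.values.index, "probe ids")
        _require_unique(self.values.columns, "sample ids")
        if not np.all(self.values.to_numpy() > 0):
            raise ValueError("intensities must be strictly positive")
        missing = set(self.values.columns) - set(self.conditions.index)
        if missing:
            raise ValueError(f"samples without a condition label: {sorted(missing)}")
        unmapped = set(self.values.index) - set(self.probe_gene.index)
        if unmapped:
            raise ValueError(f"{len(unmapped)} probes without a gene mapping")
        self.conditions = self.conditions.loc[self.values.columns]
        self.probe_gene = self.probe_gene.loc[self.values.index]

    @property
    def samples(self) -> list:
        return list(self.values.columns)

    def samples_of(self, condition: str) -> list:
        return [s for s in self.values.columns if self.conditions[s] == condition]

    def log2(self) -> pd.DataFrame:
        return np.log2(self.values)

    # --- text round-trip ---------------------------------------------------

    def write(self, outdir, prefix: str = "expression") -> None:
        os.makedirs(outdir, exist_ok=True)
        self.values.rename_axis("probe").to_csv(
            os.path.join(outdir, f"{prefix}.tsv"), sep="\t", float_format="%.6f")
        self.conditions.rename("condition").rename_axis("sample").to_csv(
            os.path.join(outdir, f"{prefix}_conditions.tsv"), sep="\t")
        self.probe_gene.rename("gene").rename_axis("probe").to_csv(
            os.path.join(outdir, f"{prefix}_probe_gene.tsv"), sep="\t")

    @classmethod
    def read(cls, outdir, prefix: str = "expression") -> "ExpressionMatrix":
        values = pd.read_csv(os.path.join(outdir, f"{prefix}.tsv"),
                             sep="\t", index_col=0)
        conditions = pd.read_csv(os.path.join(outdir, f"{prefix}_conditions.tsv"),
                                 sep="\t", index_col=0)["condition"]
        probe_gene = pd.read_csv(os.path.join(outdir, f"{prefix}_probe_gene.tsv"),
                                 sep="\t", index_col=0)["gene"]
        return cls(values=values, conditions=conditions, probe_gene=probe_gene)


@dataclass
class MirnaCountMatrix:
    """miRNA x sample integer counts with optional explicit library sizes.

    When ``library_size`` is None the per-sample column sum is used.  Explicit
    sizes may exceed the column sum (spike-ins) but never fall below 1.
    """

    counts: pd.DataFrame
    library_size: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        _require_unique(self.counts.index, "miRNA ids")
        _require_unique(self.counts.columns, "sample ids")
        arr = self.counts.to_numpy()
        if np.any(arr < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if self.library_size is not None:
            self.library_size = self.library_size.loc[self.counts.columns].astype(float)
            if np.any(self.library_size.to_numpy() < 1):
                raise ValueError("library sizes must be >= 1")

    def effective_library_size(self) -> pd.Series:
        if self.library_size is not None:
            return self.library_size
        return self.counts.sum(axis=0).astype(float)

    def write(self, outdir, prefix: str = "mirna_counts") -> None:
        os.makedirs(outdir, exist_ok=True)
        self.counts.rename_axis("mirna").to_csv(
            os.path.join(outdir, f"{prefix}.tsv"), sep="\t")

    @classmethod
    def read(cls, path) -> "MirnaCountMatrix":
        counts = pd.read_csv(path, sep="\t", index_col=0)
        return cls(counts=counts)
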