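#!/usr/bin/env python
"""Quantify the rescue: quadrant table and summary metrics.

Intersects the two DE sets, classifies each gene by the signs of its two
log2 fold changes, and reports the share of the perturbation signature moved
by the treatment, the share moved in the opposite direction (QII + QIV), and
the anticorrelation of the two fold-change axes.
"""

import argparse
import dataclasses
import os
import sys

import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from mirrescue import ContrastResult  # noqa: E402
from mirrescue.io import dump_json  # noqa: E402
from mirrescue.rescue import build_quadrant_table, rescue_metrics  # noqa: E402


def _load(path):
    table = pd.read_csv(path, sep="\t", index_col=0)
    return ContrastResult(table=table, group_a="A", group_b="B",
                          method="file", fc_threshold=1.3, p_threshold=0.05,
                          q_threshold=0.05)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", default="results")
    args = ap.parse_args()

    c1 = _load(os.path.join(args.outdir,
                            "contrast_perturbed_vs_control.tsv"))
    c2 = _load(os.path.join(args.outdir,
                            "contrast_treated_vs_perturbed.tsv"))
    de1 = set(c1.table.index[c1.table["de"]])
    de2 = set(c2.table.index[c2.table["de"]])
    table = build_quadrant_table(c1, c2, de1, de2)
    metrics = rescue_metrics(table, len(de1))

    table.to_csv(os.path.join(args.outdir, "quadrant_table.tsv"), sep="\t",
                 float_format="%.6g")
    dump_json(dataclasses.asdict(metrics),
              os.path.join(args.outdir, "rescue_metrics.json"))

    print(f"{metrics.n_intersect} of {metrics.n_altered} "
          f"perturbation-DE genes also respond to treatment "
          f"({metrics.fraction_affected:.1%})")
    print(f"inversely modulated (QII+QIV): {metrics.fraction_inverse:.1%}; "
          f"quadrants {metrics.quadrant_counts}")
    print(f"Pearson r of the fold-change pairs: {metrics.pearson_r:.3f} "
          f"(p = {metrics.pearson_p:.3g})")


if __name__ == "__main__":
    main()
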