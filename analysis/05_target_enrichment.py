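#!/usr/bin/env python
"""Predict canonical miRNA targets and test quadrant enrichment.

Scans every 3'UTR for canonical seed sites (>= 1 8mer/7mer-m8 site calls a
target), then asks whether predicted targets are over-represented among the
up-then-reverted genes (QII) and under-represented among the down-then-
reverted genes (QIV), against the background of all measured genes.
"""

import argparse
import dataclasses
import os
import sys

import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from mirrescue import MIR19A  # noqa: E402
from mirrescue.io import dump_json, read_fasta  # noqa: E402
from mirrescue.targets import predict_targets, quadrant_enrichment  # noqa: E402


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", default="results")
    ap.add_argument("--mirna", default=MIR19A)
    args = ap.parse_args()
    datadir = os.path.join(args.outdir, "data")

    utrs = read_fasta(os.path.join(datadir, "utrs.fasta"))
    predicted = predict_targets(args.mirna, utrs)
    quad = pd.read_csv(os.path.join(args.outdir, "quadrant_table.tsv"),
                       sep="\t", index_col=0)
    gene_matrix = pd.read_csv(os.path.join(args.outdir,
                                           "gene_log2_matrix.tsv"),
                              sep="\t", index_col=0)
    background = set(gene_matrix.index)
    enr = quadrant_enrichment(quad, predicted, background)

    dump_json({q: dataclasses.asdict(r) for q, r in enr.items()},
              os.path.join(args.outdir, "quadrant_enrichment.json"))
    with open(os.path.join(args.outdir, "predicted_targets.txt"), "w") as fh:
        fh.write("\n".join(sorted(predicted)) + "\n")

    print(f"{len(predicted)} predicted targets among "
          f"{len(background)} measured genes")
    q2, q4 = enr["QII"], enr["QIV"]
    print(f"QII (up, reverted): {q2.k}/{q2.n} targets, "
          f"over-enrichment p = {q2.p_over:.3g}")
    print(f"QIV (down, reverted): {q4.k}/{q4.n} targets, "
          f"depletion p = {q4.p_under:.3g}")


if __name__ == "__main__":
    main()
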