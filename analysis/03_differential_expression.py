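#!/usr/bin/env python
"""Gene-level differential expression for the two study contrasts.

Summarizes probes to genes (mean log2), then tests perturbed vs control and
treated vs perturbed (Welch t by default), adjusting with Benjamini-Hochberg
and calling DE at FC > 1.3, p < 0.05, q < 0.05.
"""

import argparse
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from mirrescue import ExpressionMatrix  # noqa: E402
from mirrescue.diffexpr import contrast, summarize_probes  # noqa: E402


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", default="results")
    ap.add_argument("--method", default="welch",
                    choices=["welch", "moderated"])
    args = ap.parse_args()
    datadir = os.path.join(args.outdir, "data")

    expr = ExpressionMatrix.read(datadir)
    gene_matrix = summarize_probes(expr)
    gene_matrix.to_csv(os.path.join(args.outdir, "gene_log2_matrix.tsv"),
                       sep="\t", float_format="%.6f")

    c1 = contrast(gene_matrix, expr.samples_of("control"),
                  expr.samples_of("perturbed"), method=args.method,
                  label_a="control", label_b="perturbed")
    c2 = contrast(gene_matrix, expr.samples_of("perturbed"),
                  expr.samples_of("treated"), method=args.method,
                  label_a="perturbed", label_b="treated")
    c1.write(os.path.join(args.outdir, "contrast_perturbed_vs_control.tsv"))
    c2.write(os.path.join(args.outdir, "contrast_treated_vs_perturbed.tsv"))

    print(f"{gene_matrix.shape[0]} genes from {expr.values.shape[0]} probes "
          f"({args.method} test)")
    print(f"perturbed vs control: {len(c1.de_set())} DE genes")
    print(f"treated vs perturbed: {len(c2.de_set())} DE genes")


if __name__ == "__main__":
    main()
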