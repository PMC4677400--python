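#!/usr/bin/env python
"""Global expression structure: AU-bootstrap dendrogram and PCA.

Clusters the nine samples on correlation distance of log2 probe intensities
with multiscale-bootstrap AU/BP clade support (1000 resamples x 10 scales),
runs covariance PCA, and selects the top decile of probes by |PC1 loading|.
"""

import argparse
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from mirrescue import ExpressionMatrix  # noqa: E402
from mirrescue.cluster import au_bootstrap  # noqa: E402
from mirrescue.pca import pca, select_top_loadings  # noqa: E402


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", default="results")
    ap.add_argument("--nboot", type=int, default=1000)
    args = ap.parse_args()

    expr = ExpressionMatrix.read(os.path.join(args.outdir, "data"))
    log2 = expr.log2()

    tree = au_bootstrap(log2, n_boot=args.nboot, seed=args.seed)
    with open(os.path.join(args.outdir, "dendrogram.nwk"), "w") as fh:
        fh.write(tree.to_newick() + "\n")
    print("clade support (AU | BP):")
    for clade in tree.clades:
        if 1 < len(clade.members) < log2.shape[1]:
            print(f"  {sorted(clade.members)}: {clade.au:.1f} | {clade.bp:.1f}")

    res = pca(log2)
    sel = select_top_loadings(res, quantile=0.10, probe_gene=expr.probe_gene)
    res.scores.rename_axis("sample").to_csv(
        os.path.join(args.outdir, "pca_scores.tsv"), sep="\t",
        float_format="%.6g")
    with open(os.path.join(args.outdir, "selected_probes.txt"), "w") as fh:
        fh.write("\n".join(sel.probes) + "\n")

    print(f"PC1 {res.variance_pct.iloc[0]:.1f}% / "
          f"PC2 {res.variance_pct.iloc[1]:.1f}% of total variance")
    cond = expr.conditions
    for c in ("control", "perturbed", "treated"):
        scores = res.scores.loc[cond[cond == c].index, "PC1"]
        print(f"  PC1 mean score, {c}: {scores.mean():.1f}")
    print(f"top decile of |PC1 loading|: {len(sel.probes)} probes, "
          f"{sel.weight_fraction:.1%} of total weight, "
          f"{sel.n_unique_genes} unique genes")


if __name__ == "__main__":
    main()
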