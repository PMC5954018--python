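#!/usr/bin/env python
"""Validate the sequencing fold changes by qPCR (2^-ddCt against the
reference gene) and regress the qPCR log2 fold changes on the RNA-seq
log2 fold changes.

Reads results/dataset/qpcr_ct.tsv and results/de/, writes results/qpcr/.
"""

import argparse
from pathlib import Path

import pandas as pd

from lnclink import io
from lnclink.qpcr import delta_delta_ct, fold_change_regression


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--dataset", type=Path, default=Path("results/dataset"))
    ap.add_argument("--de", type=Path, default=Path("results/de"))
    ap.add_argument("--outdir", type=Path, default=Path("results/qpcr"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    ct = io.read_table(args.dataset / "qpcr_ct.tsv",
                       {"sample_id": str, "condition": str, "target_gene": str,
                        "ct_target": float, "ct_reference": float})
    de = pd.read_csv(args.de / "de_results.tsv", sep="\t", index_col="gene_id")

    rows = []
    for gene in sorted(ct["target_gene"].unique()):
        res = delta_delta_ct(ct, target_gene=gene)
        rows.append({
            "target_gene": gene,
            "delta_delta_ct": res.delta_delta_ct,
            "fold_change": res.fold_change,
            "log2fc_qpcr": -res.delta_delta_ct,
            "log2fc_rnaseq": float(de.loc[gene, "log2fc"]) if gene in de.index
            else float("nan"),
            "anova_F": res.anova_F,
            "anova_p": res.anova_p,
        })
    table = pd.DataFrame(rows)
    table.to_csv(args.outdir / "qpcr_results.tsv", sep="\t", index=False,
                 float_format="%.6g")
    n_sig = int((table["anova_p"] < 0.05).sum())
    print(f"{len(table)} qPCR assays; {n_sig} significant at p < 0.05 (one-way ANOVA)")

    paired = table.dropna(subset=["log2fc_rnaseq"])
    reg = fold_change_regression(paired["log2fc_qpcr"].to_numpy(),
                                 paired["log2fc_rnaseq"].to_numpy())
    print(f"qPCR vs RNA-seq log2 fold changes: slope={reg['slope']:.3f}, "
          f"intercept={reg['intercept']:.3f}, r={reg['r']:.3f}, p={reg['p']:.2e}")
    pd.DataFrame([reg]).to_csv(args.outdir / "fold_change_regression.tsv",
                               sep="\t", index=False, float_format="%.6g")


if __name__ == "__main__":
    main()
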