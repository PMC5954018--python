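#!/usr/bin/env python
"""Differential expression of lncRNAs and mRNAs (case vs control).

Normalizes counts by median-of-ratios size factors, fits per-gene NB
dispersions, applies the Wald test with Benjamini-Hochberg adjustment, and
selects genes with fold change > 2 and padj < 0.05.  Reports the selected
counts per biotype, how many planted DE genes were recovered, and whether
the samples cluster by condition.

Reads results/dataset/, writes results/de/.
"""

import argparse
from pathlib import Path

from lnclink import io
from lnclink.expression import (
    cluster_expression,
    compute_rpkm,
    de_summary,
    differential_expression,
    top_branches,
    volcano_coords,
)
from lnclink.synthetic import GroundTruth


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--dataset", type=Path, default=Path("results/dataset"))
    ap.add_argument("--outdir", type=Path, default=Path("results/de"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    genes = io.read_annotation(args.dataset / "annotation.gtf")
    samples = io.read_samples(args.dataset / "samples.tsv")
    counts = io.read_counts(args.dataset / "counts.tsv", samples)
    biotypes = {g.gene_id: g.biotype for g in genes}

    de = differential_expression(counts, biotypes=biotypes)
    de.reset_index().rename(columns={"index": "gene_id"}).to_csv(
        args.outdir / "de_results.tsv", sep="\t", index=False, float_format="%.6g")
    volcano_coords(de).reset_index().to_csv(
        args.outdir / "volcano.tsv", sep="\t", index=False, float_format="%.6g")
    rpkm = compute_rpkm(counts, genes)
    rpkm.to_csv(args.outdir / "rpkm.tsv", sep="\t", float_format="%.6g")

    summary = de_summary(de)
    print(f"{summary['n_significant']} / {summary['n_genes']} genes significant "
          f"(FC > 2, padj < 0.05): {summary['n_lncRNA_significant']} lncRNAs "
          f"({summary['n_lncRNA_up']} up / {summary['n_lncRNA_down']} down), "
          f"{summary['n_mRNA_significant']} mRNAs "
          f"({summary['n_mRNA_up']} up / {summary['n_mRNA_down']} down)")

    truth = GroundTruth.from_json(args.dataset / "truth.json")
    selected = set(de.index[de["significant"]])
    planted = set(truth.de_genes)
    tp = len(selected & planted)
    print(f"planted-truth check: recall {tp}/{len(planted)} = {tp / len(planted):.2f}, "
          f"false discoveries {len(selected - planted)}")

    merges = cluster_expression(rpkm.loc[sorted(selected)], axis="samples")
    left, right = top_branches(merges)
    print(f"hierarchical clustering splits samples into {sorted(left)} | {sorted(right)}")


if __name__ == "__main__":
    main()
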