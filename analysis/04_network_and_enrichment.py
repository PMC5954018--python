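#!/usr/bin/env python
"""Integrate predicted targets with the DE mRNAs, run gene-set enrichment,
build the coding/non-coding co-expression network (Pearson r > 0.95 on
log2 RPKM), and overlap the mouse targets with the human DE gene list.

Reads results/dataset/, results/de/ and results/targets/,
writes results/network/.
"""

import argparse
from pathlib import Path

import pandas as pd

from lnclink import io
from lnclink.enrichment import enrich
from lnclink.network import (
    build_coexpression_network,
    cross_species_overlap,
    filter_targets_by_de,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--dataset", type=Path, default=Path("results/dataset"))
    ap.add_argument("--de", type=Path, default=Path("results/de"))
    ap.add_argument("--targets", type=Path, default=Path("results/targets"))
    ap.add_argument("--outdir", type=Path, default=Path("results/network"))
    ap.add_argument("--threshold", type=float, default=0.95)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    de = pd.read_csv(args.de / "de_results.tsv", sep="\t", index_col="gene_id")
    rpkm = pd.read_csv(args.de / "rpkm.tsv", sep="\t", index_col="gene_id")
    sig = de[de["significant"]]
    de_lnc_ids = set(sig.index[sig["biotype"] == "lncRNA"])
    de_mrna_ids = set(sig.index[sig["biotype"] == "mRNA"])
    directions = dict(de["direction"])

    cis = pd.read_csv(args.targets / "cis_pairs.tsv", sep="\t")
    trans = pd.read_csv(args.targets / "trans_hits.tsv", sep="\t")
    predicted = set(cis["mrna_id"]) | set(trans["mrna_id"])
    targets_de = filter_targets_by_de(predicted, de_mrna_ids)
    print(f"{len(predicted)} predicted targets, {len(targets_de)} also "
          "significantly DE (used downstream)")

    collection = io.read_gmt(args.dataset / "gene_sets.gmt")
    universe = set(de.index)
    query = {g: directions.get(g, "none") for g in sorted(targets_de)}
    enr = enrich(query, collection, universe)
    enr.to_csv(args.outdir / "enrichment.tsv", sep="\t", index=False,
               float_format="%.6g")
    top = enr.iloc[0] if len(enr) else None
    if top is not None:
        print(f"top enriched set: {top['set_id']} (k={top['k']}/{top['K']}, "
              f"padj={top['padj']:.2g}, {top['up_fraction']:.0%} up)")

    cand = sorted({(r.lnc_id, r.mrna_id) for r in cis.itertuples()
                   if r.mrna_id in targets_de}
                  | {(r.lnc_id, r.mrna_id) for r in trans.itertuples()
                     if r.mrna_id in targets_de})
    nodes, edges, summary = build_coexpression_network(
        de_lnc_ids, targets_de, rpkm, cand, directions, threshold=args.threshold)
    io.write_network(nodes, edges, args.outdir / "network.sif", format="sif")
    io.write_network(nodes, edges, args.outdir / "network.graphml", format="graphml")
    print(f"network: {summary['n_nodes']} nodes, {summary['n_edges']} edges "
          f"(r > {args.threshold}); at most "
          f"{summary['max_targets_per_lncRNA']} target(s) per lncRNA and "
          f"{summary['max_lncRNAs_per_target']} lncRNA(s) per target")

    ortho = io.read_ortholog_map(args.dataset / "orthologs.tsv")
    human = set(pd.read_csv(args.dataset / "human_de.tsv", sep="\t")["gene_id"])
    overlap = cross_species_overlap(
        {g: directions.get(g, "none") for g in sorted(targets_de)}, human, ortho)
    overlap.to_csv(args.outdir / "cross_species_overlap.tsv", sep="\t", index=False)
    common = overlap[overlap["common"]]
    print(f"cross-species overlap: {len(common)} of {len(overlap)} mouse targets "
          f"also DE in the human list: {', '.join(common['mouse_gene_id']) or 'none'}")


if __name__ == "__main__":
    main()
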