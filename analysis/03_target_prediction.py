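#!/usr/bin/env python
"""Predict the protein-coding targets of the significantly DE lncRNAs.

Cis: mRNAs whose gene span lies within 10 kb of a DE lncRNA.  Trans: mRNAs
whose sequence is complementary to a DE lncRNA (local complementarity
alignment with E-value < 1e-5 and duplex energy G < -20, E-values
calibrated on shuffled sequence pairs).  Reports both target sets, their
intersection, and the recovery of the planted pairs.

Reads results/dataset/ and results/de/, writes results/targets/.
"""

import argparse
from pathlib import Path

import pandas as pd

from lnclink import io
from lnclink.synthetic import GroundTruth
from lnclink.targets import find_cis_targets, find_trans_targets, intersect_cis_trans


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--dataset", type=Path, default=Path("results/dataset"))
    ap.add_argument("--de", type=Path, default=Path("results/de"))
    ap.add_argument("--outdir", type=Path, default=Path("results/targets"))
    ap.add_argument("--seed", type=int, default=1729)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    genes = io.read_annotation(args.dataset / "annotation.gtf")
    seqs = io.read_fasta(args.dataset / "sequences.fasta")
    de = pd.read_csv(args.de / "de_results.tsv", sep="\t", index_col="gene_id")
    sig = de[de["significant"]]
    de_lnc_ids = sorted(sig.index[sig["biotype"] == "lncRNA"])

    de_lncs = [g for g in genes if g.gene_id in set(de_lnc_ids)]
    mrnas = [g for g in genes if g.biotype == "mRNA"]
    cis = find_cis_targets(de_lncs, mrnas)
    pd.DataFrame([vars(p) for p in cis]).to_csv(
        args.outdir / "cis_pairs.tsv", sep="\t", index=False)
    print(f"cis: {len(cis)} pairs within 10 kb "
          f"({len({p.lnc_id for p in cis})} lncRNAs, "
          f"{len({p.mrna_id for p in cis})} targets)")

    trans = find_trans_targets(
        {g: seqs[g] for g in de_lnc_ids},
        {g.gene_id: seqs[g.gene_id] for g in mrnas},
        seed=args.seed)
    pd.DataFrame(
        [{"lnc_id": h.lnc_id, "mrna_id": h.mrna_id, "score": h.score,
          "energy_G": h.energy_G, "evalue": h.evalue} for h in trans]
    ).to_csv(args.outdir / "trans_hits.tsv", sep="\t", index=False,
             float_format="%.6g")
    print(f"trans: {len(trans)} hits with e < 1e-5 and G < -20 "
          f"({len({h.lnc_id for h in trans})} lncRNAs, "
          f"{len({h.mrna_id for h in trans})} targets)")

    inter = intersect_cis_trans(cis, trans)
    pd.DataFrame([{"lnc_id": l, "mrna_id": m} for l, m in inter["connections"]]
                 ).to_csv(args.outdir / "intersection.tsv", sep="\t", index=False)
    print(f"cis/trans overlap: {inter['n_lncRNAs']} lncRNAs, "
          f"{inter['n_targets']} targets, {inter['n_connections']} connections")

    truth = GroundTruth.from_json(args.dataset / "truth.json")
    cis_tp = {(p.lnc_id, p.mrna_id) for p in cis} & truth.cis_set()
    trans_tp = {(h.lnc_id, h.mrna_id) for h in trans} & truth.trans_set()
    print(f"planted-truth check: cis {len(cis_tp)}/{len(truth.cis_set())}, "
          f"trans {len(trans_tp)}/{len(truth.trans_set())} recovered")


if __name__ == "__main__":
    main()
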