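"""Recovery and calibration measurements against the generator's ground truth.

These functions re-run the pipeline's stages on freshly simulated data and
score them against the planted structure; they back both the test suite and
the reproducibility script.
"""

from __future__ import annotations

import numpy as np

from .enrichment import enrich
from .expression import compute_rpkm, differential_expression
from .models import GeneSet, GeneSetCollection
from .network import build_coexpression_network
from .synthetic import SimConfig, simulate_counts, simulate_genome
from .targets import find_cis_targets, find_trans_targets


def de_recovery(seeds: list[int], **config_kwargs) -> dict:
    """Average recall of planted DE genes and false-discovery proportion of
    the FC > 2 / padj < 0.05 selection, over independent simulations."""
    recalls, fdps = [], []
    for seed in seeds:
        cfg = SimConfig(seed=seed, **config_kwargs)
        genes, _seqs, truth = simulate_genome(cfg)
        counts = simulate_counts(cfg, genes, truth)
        table = differential_expression(counts)
        selected = set(table.index[table["significant"]])
        planted = set(truth.de_genes)
        recalls.append(len(selected & planted) / len(planted))
        fdps.append(len(selected - planted) / max(len(selected), 1))
    return {"recall": float(np.mean(recalls)), "fdp": float(np.mean(fdps)),
            "n_seeds": len(seeds)}


def cis_recovery(config: SimConfig) -> dict:
    """Recall/precision of cis prediction against the planted pairs, using
    the planted DE lncRNAs as the query set."""
    genes, _seqs, truth = simulate_genome(config)
    de_lncs = [g for g in genes
               if g.biotype == "lncRNA" and g.gene_id in truth.de_genes]
    mrnas = [g for g in genes if g.biotype == "mRNA"]
    predicted = {(p.lnc_id, p.mrna_id) for p in find_cis_targets(de_lncs, mrnas)}
    planted = truth.cis_set()
    tp = len(predicted & planted)
    return {
        "recall": tp / len(planted) if planted else 1.0,
        "precision": tp / len(predicted) if predicted else 1.0,
        "n_planted": len(planted),
    }


def trans_recovery(seeds: list[int], **config_kwargs) -> dict:
    """Average recall/precision of trans prediction against planted 30-mer
    complement pairs, over independent simulations."""
    recalls, precisions = [], []
    for seed in seeds:
        cfg = SimConfig(seed=seed, **config_kwargs)
        genes, seqs, truth = simulate_genome(cfg)
        lnc_ids = sorted(g.gene_id for g in genes
                         if g.biotype == "lncRNA" and g.gene_id in truth.de_genes)
        lnc_seqs = {g: seqs[g] for g in lnc_ids}
        mrna_seqs = {g.gene_id: seqs[g.gene_id] for g in genes if g.biotype == "mRNA"}
        hits = {(h.lnc_id, h.mrna_id)
                for h in find_trans_targets(lnc_seqs, mrna_seqs, seed=seed)}
        planted = truth.trans_set()
        tp = len(hits & planted)
        recalls.append(tp / len(planted))
        precisions.append(tp / max(len(hits), 1))
    return {"recall": float(np.mean(recalls)),
            "precision": float(np.mean(precisions)), "n_seeds": len(seeds)}


def correlation_block_recovery(config: SimConfig, threshold: float = 0.95) -> dict:
    """Fraction of planted correlation-block edges retained at r > threshold."""
    genes, _seqs, truth = simulate_genome(config)
    counts = simulate_counts(config, genes, truth)
    rpkm = compute_rpkm(counts, genes)
    cand = [tuple(b["members"]) for b in truth.corr_blocks]
    lncs = {c[0] for c in cand}
    tgts = {c[1] for c in cand}
    _nodes, edges, _summary = build_coexpression_network(
        lncs, tgts, rpkm, cand, {}, threshold=threshold)
    return {"edge_recall": len(edges) / len(cand) if cand else 1.0,
            "n_planted_edges": len(cand)}


def null_type1_error(seed: int, n_genes: int = 5000, dispersion: float = 0.1) -> dict:
    """Rejection rate of the Wald DE test at p < 0.05 under the null."""
    n_lnc = n_genes // 5
    cfg = SimConfig(seed=seed, n_lnc=n_lnc, n_mrna=n_genes - n_lnc,
                    planted_de_fraction=0.0, n_cis_pairs=0, n_trans_pairs=0,
                    n_anchor_pairs=0, n_corr_blocks=0, dispersion=dispersion)
    genes, _seqs, truth = simulate_genome(cfg)
    counts = simulate_counts(cfg, genes, truth)
    table = differential_expression(counts)
    return {"rate": float((table["p"] < 0.05).mean()), "n_genes": n_genes}


def enrichment_null_rate(seed: int, n_replicates: int = 40, n_universe: int = 2000,
                         n_sets: int = 40, query_size: int = 250) -> dict:
    """Fraction of gene sets reaching p < 0.05 for random queries.

    Sets are made large (150-300 members in a 2000-gene universe) so the
    discrete hypergeometric p-values are nearly uniform under the null.
    """
    rng = np.random.default_rng(seed)
    universe = [f"g{i}" for i in range(n_universe)]
    sets = []
    for i in range(n_sets):
        size = int(rng.integers(150, 300))
        members = rng.choice(universe, size=size, replace=False)
        sets.append(GeneSet(f"S{i}", "", frozenset(str(m) for m in members)))
    collection = GeneSetCollection(sets=sets)
    rates = []
    for _ in range(n_replicates):
        query = {str(g) for g in rng.choice(universe, size=query_size, replace=False)}
        res = enrich(query, collection, set(universe))
        rates.append(float((res["p"] < 0.05).mean()))
    return {"rate": float(np.mean(rates)),
            "n_tests": n_replicates * n_sets}
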