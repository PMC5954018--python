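"""End-to-end orchestration: dataset simulation and the full analysis run.

``run_pipeline`` chains the stages in their methodological order -- DE ->
cis/trans target prediction -> intersection -> DE-mRNA filtering ->
enrichment -> co-expression network -> cross-species overlap -> qPCR
comparison -- and writes one table per stage plus a run manifest.  Given
the same inputs and seed the outputs are byte-identical.  A stage failure
aborts with the stage name; files already written by the failed run are
renamed with a ``.partial`` suffix.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .enrichment import enrich
from .expression import (
    cluster_expression,
    compute_rpkm,
    de_summary,
    differential_expression,
    top_branches,
    volcano_coords,
)
from .models import ValidationError
from .network import (
    build_coexpression_network,
    cross_species_overlap,
    filter_targets_by_de,
)
from .qpcr import delta_delta_ct, fold_change_regression
from .synthetic import GroundTruth, SimConfig, simulate_counts, simulate_genome, simulate_qpcr
from .targets import find_cis_targets, find_trans_targets, intersect_cis_trans

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    """Input paths, thresholds and run settings for a full analysis."""

    annotation: str
    fasta: str
    counts: str
    samples: str
    outdir: str
    gene_sets: str | None = None
    orthologs: str | None = None
    human_de: str | None = None
    qpcr_ct: str | None = None
    fold_change: float = 2.0
    alpha: float = 0.05
    cis_gap: int = 10_000
    evalue: float = 1e-5
    energy: float = -20.0
    corr: float = 0.95
    absolute_corr: bool = False
    seed: int = 1729

    def __post_init__(self) -> None:
        if self.fold_change <= 0 or not (0 < self.alpha < 1):
            raise ValidationError("fold_change must be > 0 and alpha in (0, 1)")
        if self.cis_gap <= 0 or self.evalue <= 0 or not (0 < self.corr <= 1):
            raise ValidationError("thresholds must be positive (corr in (0, 1])")
        self.seed = int(self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; return the manifest (also written to disk)."""
    required = [config.annotation, config.fasta, config.counts, config.samples]
    optional = [config.gene_sets, config.orthologs, config.human_de, config.qpcr_ct]
    for p in required + [p for p in optional if p]:
        if not Path(p).exists():
            raise ValidationError(f"input file not found: {p}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "stages": {},
    }

    def emit(name: str, df: pd.DataFrame, index: bool = False) -> Path:
        path = outdir / name
        _write_tsv(df, path, index=index)
        written.append(path)
        return path

    stage = "load_inputs"
    try:
        genes = io.read_annotation(config.annotation, format="gtf")
        sequences = io.read_fasta(config.fasta)
        samples = io.read_samples(config.samples)
        counts = io.read_counts(config.counts, samples)
        biotypes = {g.gene_id: g.biotype for g in genes}
        gene_by_id = {g.gene_id: g for g in genes}
        missing = [gid for gid in counts.gene_ids if gid not in gene_by_id]
        if missing:
            raise ValidationError(f"counted genes missing from annotation: {missing[:5]}")
        manifest["stages"][stage] = {
            "n_genes": len(genes),
            "n_samples": len(samples.sample_ids),
        }

        stage = "differential_expression"
        de = differential_expression(
            counts, biotypes=biotypes,
            fold_change=config.fold_change, alpha=config.alpha,
        )
        de_out = de.reset_index().rename(columns={"index": "gene_id"})
        emit("de_results.tsv", de_out)
        emit("volcano.tsv", volcano_coords(de).reset_index())
        rpkm = compute_rpkm(counts, genes)
        emit("rpkm.tsv", rpkm, index=True)
        sig = de[de["significant"]]
        de_lnc_ids = sorted(sig.index[sig["biotype"] == "lncRNA"])
        de_mrna_ids = sorted(sig.index[sig["biotype"] == "mRNA"])
        if len(sig) >= 2:
            merges = cluster_expression(rpkm.loc[sig.index], axis="samples")
            left, right = top_branches(merges)
            emit("sample_clusters.tsv", pd.DataFrame(
                {"branch": ["A"] * len(left) + ["B"] * len(right),
                 "sample_id": sorted(left) + sorted(right)}))
        manifest["stages"][stage] = de_summary(de)

        stage = "cis_targets"
        de_lncs = [gene_by_id[g] for g in de_lnc_ids]
        mrnas = [g for g in genes if g.biotype == "mRNA"]
        cis = find_cis_targets(de_lncs, mrnas, max_gap_bp=config.cis_gap)
        emit("cis_pairs.tsv", pd.DataFrame(
            [{"lnc_id": p.lnc_id, "mrna_id": p.mrna_id, "gap_bp": p.gap_bp} for p in cis],
            columns=["lnc_id", "mrna_id", "gap_bp"]))
        manifest["stages"][stage] = {"n_pairs": len(cis)}

        stage = "trans_targets"
        lnc_seqs = {}
        for gid in de_lnc_ids:
            if gid not in sequences:
                raise ValidationError(f"missing sequence for lncRNA {gid!r}")
            lnc_seqs[gid] = sequences[gid]
        mrna_seqs = {g.gene_id: sequences[g.gene_id] for g in mrnas
                     if g.gene_id in sequences}
        trans = find_trans_targets(
            lnc_seqs, mrna_seqs,
            evalue_threshold=config.evalue, energy_threshold=config.energy,
            seed=config.seed,
        )
        emit("trans_hits.tsv", pd.DataFrame(
            [{"lnc_id": h.lnc_id, "mrna_id": h.mrna_id, "score": h.score,
              "energy_G": h.energy_G, "evalue": h.evalue,
              "lnc_start": h.alignment[0], "lnc_end": h.alignment[1],
              "mrna_start": h.alignment[2], "mrna_end": h.alignment[3]}
             for h in trans],
            columns=["lnc_id", "mrna_id", "score", "energy_G", "evalue",
                     "lnc_start", "lnc_end", "mrna_start", "mrna_end"]))
        manifest["stages"][stage] = {"n_hits": len(trans)}

        stage = "cis_trans_intersection"
        inter = intersect_cis_trans(cis, trans)
        emit("cis_trans_intersection.tsv", pd.DataFrame(
            [{"lnc_id": l, "mrna_id": m} for l, m in inter["connections"]],
            columns=["lnc_id", "mrna_id"]))
        manifest["stages"][stage] = {
            "n_lncRNAs": inter["n_lncRNAs"],
            "n_targets": inter["n_targets"],
            "n_connections": inter["n_connections"],
        }

        stage = "target_de_filter"
        predicted = {p.mrna_id for p in cis} | {h.mrna_id for h in trans}
        targets_de = filter_targets_by_de(predicted, set(de_mrna_ids))
        directions = dict(de["direction"])
        emit("targets_de.tsv", pd.DataFrame(
            [{"gene_id": g, "direction": directions.get(g, "none")}
             for g in sorted(targets_de)],
            columns=["gene_id", "direction"]))
        manifest["stages"][stage] = {
            "n_predicted_targets": len(predicted),
            "n_de_filtered_targets": len(targets_de),
        }

        if config.gene_sets:
            stage = "enrichment"
            collection = io.read_gmt(config.gene_sets)
            universe = {gid for gid in counts.gene_ids
                        if counts.counts.loc[gid].sum() > 0}
            query = {g: directions.get(g, "none") for g in sorted(targets_de)}
            enr = enrich(query, collection, universe)
            emit("enrichment.tsv", enr)
            manifest["stages"][stage] = {
                "n_sets_tested": int(len(enr)),
                "n_sets_significant": int((enr["padj"] < config.alpha).sum())
                if len(enr) else 0,
            }

        stage = "coexpression_network"
        candidate_conn = sorted(
            {(p.lnc_id, p.mrna_id) for p in cis if p.mrna_id in targets_de}
            | {(h.lnc_id, h.mrna_id) for h in trans if h.mrna_id in targets_de}
        )
        nodes, edges, net_summary = build_coexpression_network(
            set(de_lnc_ids), targets_de, rpkm, candidate_conn, directions,
            threshold=config.corr, absolute=config.absolute_corr,
        )
        io.write_network(nodes, edges, outdir / "network.sif", format="sif")
        written += [outdir / "network.sif",
                    outdir / "network.sif.attrs.tsv"]
        io.write_network(nodes, edges, outdir / "network.graphml", format="graphml")
        written.append(outdir / "network.graphml")
        manifest["stages"][stage] = net_summary

        overlap_common: set[str] = set()
        if config.orthologs and config.human_de:
            stage = "cross_species_overlap"
            ortho = io.read_ortholog_map(config.orthologs)
            human = set(
                io.read_table(config.human_de, {"gene_id": str})["gene_id"]
            )
            mouse_targets = {g: directions.get(g, "none") for g in sorted(targets_de)}
            overlap = cross_species_overlap(mouse_targets, human, ortho)
            emit("cross_species_overlap.tsv", overlap)
            overlap_common = set(overlap.loc[overlap["common"], "mouse_gene_id"])
            manifest["stages"][stage] = {
                "n_targets": int(len(overlap)),
                "n_unmapped": int((~overlap["mapped"]).sum()),
                "n_common": int(overlap["common"].sum()),
            }

        qpcr_rows: list[dict] = []
        if config.qpcr_ct:
            stage = "qpcr_validation"
            ct = io.read_table(
                config.qpcr_ct,
                {"sample_id": str, "condition": str, "target_gene": str,
                 "ct_target": float, "ct_reference": float},
            )
            for gene in sorted(ct["target_gene"].unique()):
                res = delta_delta_ct(ct, target_gene=gene)
                qpcr_rows.append({
                    "target_gene": gene,
                    "delta_delta_ct": res.delta_delta_ct,
                    "fold_change": res.fold_change,
                    "log2fc_qpcr": -res.delta_delta_ct,
                    "anova_F": res.anova_F,
                    "anova_p": res.anova_p,
                })
            qpcr_df = pd.DataFrame(qpcr_rows)
            qpcr_df["log2fc_rnaseq"] = [
                float(de.loc[g, "log2fc"]) if g in de.index else np.nan
                for g in qpcr_df["target_gene"]
            ]
            emit("qpcr_results.tsv", qpcr_df)
            paired = qpcr_df.dropna(subset=["log2fc_rnaseq"])
            stage_info: dict = {"n_assays": int(len(qpcr_df))}
            if len(paired) >= 3:
                reg = fold_change_regression(
                    paired["log2fc_qpcr"].to_numpy(),
                    paired["log2fc_rnaseq"].to_numpy(),
                )
                stage_info["regression"] = reg
            manifest["stages"][stage] = stage_info

        stage = "prioritized_pairs"
        edge_set = {(u, v) for u, v, _r in edges}
        prioritized = [
            {"lnc_id": l, "mrna_id": m,
             "lnc_direction": directions.get(l, ""),
             "mrna_direction": directions.get(m, ""),
             "in_human_overlap": m in overlap_common}
            for l, m in inter["connections"]
            if l in de_lnc_ids and m in targets_de and (l, m) in edge_set
        ]
        emit("prioritized_pairs.tsv", pd.DataFrame(
            prioritized,
            columns=["lnc_id", "mrna_id", "lnc_direction", "mrna_direction",
                     "in_human_overlap"]))
        manifest["stages"][stage] = {"n_pairs": len(prioritized)}
    except Exception as exc:  # noqa: BLE001 - any stage failure aborts the run
        for path in written:
            if path.exists():
                path.rename(path.with_name(path.name + ".partial"))
        raise StageError(stage, exc) from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    logger.info("pipeline complete: %s", outdir)
    return manifest


# -- synthetic dataset emission --------------------------------------------

def simulate_dataset(
    config: SimConfig,
    outdir: str | Path,
    qpcr_noise_sd: float = 0.15,
    n_qpcr_reps: int = 8,
    n_gene_sets: int = 20,
    n_human_extra: int = 30,
) -> dict:
    """Write a complete synthetic dataset (the formats the pipeline reads)
    plus a ``truth.json`` ground-truth sidecar and a file manifest.

    Besides annotation/sequences/counts/samples this derives the auxiliary
    inputs: gene sets (random sets plus one set collecting the planted DE
    mRNAs, so enrichment has signal to find), an ortholog map for every
    mRNA, a human DE list containing the orthologs of anchor targets plus
    noise, and a qPCR plate for the anchor pair and a panel of planted DE
    genes with their true fold changes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes, sequences, truth = simulate_genome(config)
    counts = simulate_counts(config, genes, truth)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))

    io.write_annotation(genes, outdir / "annotation.gtf", format="gtf")
    io.write_fasta(sequences, outdir / "sequences.fasta")
    io.write_counts(counts, outdir / "counts.tsv")
    io.write_samples(counts.samples, outdir / "samples.tsv")
    truth.to_json(outdir / "truth.json")

    # gene sets: random draws from all genes + one set of planted DE mRNAs
    all_ids = [g.gene_id for g in genes]
    from .models import GeneSet, GeneSetCollection

    sets = []
    for i in range(n_gene_sets):
        size = int(rng.integers(10, 40))
        members = rng.choice(all_ids, size=size, replace=False)
        sets.append(GeneSet(f"RS{i + 1:03d}", f"random set {i + 1}",
                            frozenset(str(m) for m in members)))
    de_mrnas = sorted(g for g, _d in truth.de_genes.items() if g.startswith("pcg"))
    if len(de_mrnas) >= 3:
        sets.append(GeneSet("PLANTED_DE_MRNA", "planted DE protein-coding genes",
                            frozenset(de_mrnas)))
    io.write_gmt(GeneSetCollection(sets=sets), outdir / "gene_sets.gmt")

    # ortholog map: every mRNA has a human ortholog
    mrna_ids = sorted(g.gene_id for g in genes if g.biotype == "mRNA")
    with open(outdir / "orthologs.tsv", "w") as fh:
        fh.write("mouse_gene_id\thuman_gene_id\n")
        for mid in mrna_ids:
            fh.write(f"{mid}\t{mid.upper().replace('PCG', 'HUM')}\n")

    # human DE list: orthologs of anchor targets + planted DE mRNAs + noise
    human_hits = {p["mrna"] for p in truth.anchor_pairs}
    human_hits |= set(rng.choice(de_mrnas, size=min(5, len(de_mrnas)), replace=False))
    human_ids = sorted(m.upper().replace("PCG", "HUM") for m in human_hits)
    extra = [f"HUMX{i:04d}" for i in range(1, n_human_extra + 1)]
    with open(outdir / "human_de.tsv", "w") as fh:
        fh.write("gene_id\n")
        for hid in human_ids + extra:
            fh.write(f"{hid}\n")

    # qPCR plate: anchor pair + a panel of planted DE genes + one null gene
    panel = sorted({p["lnc"] for p in truth.anchor_pairs}
                   | {p["mrna"] for p in truth.anchor_pairs})
    de_rest = sorted(set(truth.de_genes) - set(panel))
    panel += list(rng.choice(de_rest, size=min(8, len(de_rest)), replace=False))
    null_genes = sorted(set(all_ids) - set(truth.de_genes))
    if null_genes:
        panel.append(str(rng.choice(null_genes)))
    fold_changes = {}
    for g in panel:
        d = truth.de_genes.get(g)
        if d is None:
            fold_changes[g] = 1.0
        else:
            fold_changes[g] = float(2.0 ** (config.planted_log2fc if d == "up"
                                            else -config.planted_log2fc))
    qpcr = simulate_qpcr(fold_changes, n_reps=n_qpcr_reps,
                         seed=config.seed, noise_sd=qpcr_noise_sd)
    _write_tsv(qpcr, outdir / "qpcr_ct.tsv")

    files = sorted(p.name for p in outdir.iterdir() if p.is_file())
    manifest = {
        "seed": config.seed,
        "config": asdict(config),
        "files": files,
        "n_genes": len(genes),
        "n_planted_de": len(truth.de_genes),
        "n_cis_pairs": len(truth.cis_pairs),
        "n_trans_pairs": len(truth.trans_pairs),
        "n_corr_blocks": len(truth.corr_blocks),
        "n_anchor_pairs": len(truth.anchor_pairs),
    }
    with open(outdir / "dataset_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def pipeline_config_for_dataset(dataset_dir: str | Path, outdir: str | Path,
                                seed: int = 1729, **overrides) -> PipelineConfig:
    """Convenience: a PipelineConfig wired to a simulate_dataset directory."""
    d = Path(dataset_dir)
    defaults = dict(
        annotation=str(d / "annotation.gtf"),
        fasta=str(d / "sequences.fasta"),
        counts=str(d / "counts.tsv"),
        samples=str(d / "samples.tsv"),
        gene_sets=str(d / "gene_sets.gmt"),
        orthologs=str(d / "orthologs.tsv"),
        human_de=str(d / "human_de.tsv"),
        qpcr_ct=str(d / "qpcr_ct.tsv"),
        outdir=str(outdir),
        seed=seed,
    )
    defaults.update(overrides)
    return PipelineConfig(**defaults)
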