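"""Synthetic dataset generator with planted, recoverable structure.

Emulates the inputs of a two-group (3 control vs 3 case) bulk RNA-seq
comparison of lncRNAs and mRNAs, with ground truth recorded for every
planted feature so each downstream stage can be tested for recovery:

* negative-binomial counts (variance mu + alpha mu^2) with log-uniform
  per-sample size factors;
* planted differentially expressed genes at a fixed |log2 fold change|;
* cis pairs: a lncRNA placed within 10 kb of an mRNA, all other
  opposite-biotype neighbours kept >= 20 kb apart;
* trans pairs: a lncRNA carrying the exact reverse complement of a segment
  of its partner mRNA (otherwise i.i.d. uniform ACGT sequence);
* correlation blocks: genes sharing a lognormal latent factor scaled so
  pairwise Pearson correlation of log expression is approximately
  ``corr_target``;
* anchor pairs: a single lncRNA-mRNA pair planted to survive every
  pipeline stage at once (DE on both sides, cis, trans, and tightly
  correlated counts via a Gaussian copula), mirroring the kind of
  lncRNA-target candidate the pipeline is meant to surface;
* qPCR Ct plates consistent with chosen fold changes, normalized against a
  constant-Ct reference gene.

One independent RNG stream per artifact (genome, counts, qPCR) is derived
from the master seed, so each can be regenerated on its own.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .models import CountMatrix, GeneModel, SampleTable, ValidationError


@dataclass
class SimConfig:
    seed: int = 1729
    n_lnc: int = 60
    n_mrna: int = 120
    n_control: int = 3
    n_case: int = 3
    base_mean_range: tuple[float, float] = (50.0, 2000.0)
    dispersion: float = 0.1
    planted_de_fraction: float = 0.25
    planted_log2fc: float = 2.0
    n_cis_pairs: int = 6
    n_trans_pairs: int = 6
    trans_motif_len: int = 30
    n_corr_blocks: int = 2
    corr_target: float = 0.99
    # generator-internal knobs
    n_anchor_pairs: int = 1
    n_decoy_trans: int = 0
    decoy_motif_len: int = 12
    lnc_length: int = 300
    mrna_length: int = 500
    corr_block_mean: float = 50_000.0
    anchor_noise_corr: float = 0.995
    intergenic_spacing: int = 25_000
    genes_per_chrom: int = 40
    chrom_length_bp: int | None = None
    size_factor_range: tuple[float, float] = (0.5, 2.0)

    def __post_init__(self) -> None:
        if self.n_control < 2 or self.n_case < 2:
            raise ValidationError("need >= 2 replicates per group")
        if not (0 <= self.planted_de_fraction < 1):
            raise ValidationError("planted_de_fraction must be in [0, 1)")
        if self.planted_de_fraction > 0 and self.planted_log2fc < 1:
            raise ValidationError("planted_log2fc must be >= 1")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        if not (0 < self.corr_target <= 1):
            raise ValidationError("corr_target must be in (0, 1]")
        if self.n_cis_pairs > min(self.n_lnc, self.n_mrna):
            raise ValidationError("n_cis_pairs exceeds min(n_lnc, n_mrna)")
        n_de_lnc = int(round(self.planted_de_fraction * self.n_lnc))
        need = self.n_cis_pairs + self.n_trans_pairs + self.n_anchor_pairs
        if self.planted_de_fraction > 0 and need > n_de_lnc:
            raise ValidationError(
                f"{need} planted pair lncRNAs exceed the {n_de_lnc} planted DE lncRNAs"
            )
        if self.trans_motif_len > min(self.lnc_length, self.mrna_length):
            raise ValidationError("trans_motif_len exceeds sequence length")
        if self.intergenic_spacing < 20_000:
            raise ValidationError("intergenic_spacing must keep non-pairs >= 20 kb apart")

    def streams(self) -> dict[str, np.random.Generator]:
        genome, counts, qpcr = np.random.SeedSequence(self.seed).spawn(3)
        return {
            "genome": np.random.default_rng(genome),
            "counts": np.random.default_rng(counts),
            "qpcr": np.random.default_rng(qpcr),
        }


@dataclass
class GroundTruth:
    """Planted structure: what a perfect pipeline should recover."""

    de_genes: dict[str, str] = field(default_factory=dict)  # gene_id -> up|down
    cis_pairs: list[dict] = field(default_factory=list)  # lnc, mrna, gap_bp
    trans_pairs: list[dict] = field(default_factory=list)  # lnc, mrna, motif coords
    decoy_trans_pairs: list[dict] = field(default_factory=list)
    corr_blocks: list[dict] = field(default_factory=list)  # members, loading_log2
    anchor_pairs: list[dict] = field(default_factory=list)  # lnc, mrna

    def cis_set(self) -> set[tuple[str, str]]:
        return {(p["lnc"], p["mrna"]) for p in self.cis_pairs}

    def trans_set(self) -> set[tuple[str, str]]:
        return {(p["lnc"], p["mrna"]) for p in self.trans_pairs}

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _block_loading(config: SimConfig) -> float:
    """Latent-factor loading (log2 scale) achieving ``corr_target``.

    Pairwise Pearson r of two block members' log2 expression is
    tau^2 / (tau^2 + v) with v the per-gene noise variance.  v itself
    depends on tau because a low factor draw pushes the NB mean down and
    inflates Poisson noise, E[1/mu] = exp((tau ln2)^2 / 2) / mu0 for a
    lognormal factor; the loading is solved by fixed-point iteration.
    """
    if config.corr_target >= 1:
        ratio = 1e6
    else:
        ratio = config.corr_target / (1.0 - config.corr_target)
    ln2 = np.log(2.0)
    tau = 0.0
    for _ in range(100):
        inv_mu = np.exp((tau * ln2) ** 2 / 2.0) / config.corr_block_mean
        v = (config.dispersion + inv_mu) / ln2**2
        new_tau = float(np.sqrt(ratio * v))
        if not np.isfinite(new_tau) or new_tau > 50:
            raise ValidationError(
                "corr_target unattainable: raise corr_block_mean or lower corr_target"
            )
        if abs(new_tau - tau) < 1e-9:
            return new_tau
        tau = new_tau
    return tau


_ALPHABET = np.array(list("ACGT"))
_RC = str.maketrans("ACGT", "TGCA")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_ALPHABET, size=length))


def simulate_genome(
    config: SimConfig,
) -> tuple[list[GeneModel], dict[str, str], GroundTruth]:
    """Generate the annotation, sequences and ground truth.

    Genes are placed left-to-right on synthetic chromosomes.  Planted cis
    (and anchor) pairs sit adjacent with a gap drawn uniformly from
    [0, 9999] bp; every other pair of neighbouring genes is separated by at
    least ``intergenic_spacing`` (>= 20 kb), so only planted pairs satisfy
    the 10-kb rule.  Trans (and anchor) lncRNAs carry the exact reverse
    complement of a ``trans_motif_len`` segment of their partner mRNA.
    """
    rng = config.streams()["genome"]
    truth = GroundTruth()

    lnc_ids = [f"lnc{i:04d}" for i in range(1, config.n_lnc + 1)]
    mrna_ids = [f"pcg{i:04d}" for i in range(1, config.n_mrna + 1)]

    # ---- planted DE genes and their directions
    n_de_lnc = int(round(config.planted_de_fraction * config.n_lnc))
    n_de_mrna = int(round(config.planted_de_fraction * config.n_mrna))
    de_lncs = list(rng.choice(lnc_ids, size=n_de_lnc, replace=False))
    de_mrnas = list(rng.choice(mrna_ids, size=n_de_mrna, replace=False))
    for g in de_lncs + de_mrnas:
        truth.de_genes[g] = "up" if rng.random() < 0.5 else "down"

    # ---- assign roles: anchor, cis, trans lncRNAs all come from the DE set
    de_lnc_pool = list(de_lncs)
    rng.shuffle(de_lnc_pool)
    anchor_lncs = [de_lnc_pool.pop() for _ in range(config.n_anchor_pairs)]
    cis_lncs = [de_lnc_pool.pop() for _ in range(config.n_cis_pairs)]
    trans_lncs = [de_lnc_pool.pop() for _ in range(config.n_trans_pairs)]

    de_mrna_pool = list(de_mrnas)
    rng.shuffle(de_mrna_pool)
    anchor_mrnas = [de_mrna_pool.pop() for _ in range(config.n_anchor_pairs)]
    # plain cis/trans targets come from the remaining mRNAs (DE or not)
    other_mrnas = [m for m in mrna_ids if m not in set(anchor_mrnas)]
    rng.shuffle(other_mrnas)
    cis_mrnas = [other_mrnas.pop() for _ in range(config.n_cis_pairs)]
    trans_mrnas = [other_mrnas.pop() for _ in range(config.n_trans_pairs)]
    decoy_lnc_pool = [l for l in lnc_ids
                      if l not in set(anchor_lncs + cis_lncs + trans_lncs)]
    rng.shuffle(decoy_lnc_pool)
    decoy_lncs = [decoy_lnc_pool.pop() for _ in range(config.n_decoy_trans)]
    decoy_mrnas = [other_mrnas.pop() for _ in range(config.n_decoy_trans)]

    # anchors are forced to the same direction on both sides (co-regulation)
    for lnc, mrna in zip(anchor_lncs, anchor_mrnas):
        direction = "up" if rng.random() < 0.5 else "down"
        truth.de_genes[lnc] = direction
        truth.de_genes[mrna] = direction
        truth.anchor_pairs.append({"lnc": lnc, "mrna": mrna})

    # ---- correlation blocks use dedicated non-DE, non-paired genes
    paired = set(anchor_lncs + cis_lncs + trans_lncs + anchor_mrnas
                 + cis_mrnas + trans_mrnas + decoy_lncs + decoy_mrnas)
    free_lncs = [g for g in lnc_ids if g not in paired and g not in truth.de_genes]
    free_mrnas = [g for g in mrna_ids if g not in paired and g not in truth.de_genes]
    if config.n_corr_blocks > min(len(free_lncs), len(free_mrnas)):
        raise ValidationError("not enough unassigned genes for correlation blocks")
    loading = _block_loading(config) if config.n_corr_blocks > 0 else 0.0
    block_lncs = list(rng.choice(free_lncs, size=config.n_corr_blocks, replace=False))
    block_mrnas = list(rng.choice(free_mrnas, size=config.n_corr_blocks, replace=False))
    for bl, bm in zip(block_lncs, block_mrnas):
        truth.corr_blocks.append({"members": [bl, bm], "loading_log2": loading})

    # ---- genomic placement
    length_of = {g: (config.lnc_length if g.startswith("lnc") else config.mrna_length)
                 for g in lnc_ids + mrna_ids}
    pair_units = [(l, m) for l, m in zip(anchor_lncs, anchor_mrnas)]
    pair_units += list(zip(cis_lncs, cis_mrnas))
    paired_genes = {g for unit in pair_units for g in unit}
    single_units = [(g,) for g in lnc_ids + mrna_ids if g not in paired_genes]
    units: list[tuple[str, ...]] = pair_units + single_units
    rng.shuffle(units)

    genes: list[GeneModel] = []
    gaps: dict[tuple[str, str], int] = {}
    chrom_idx, placed_on_chrom, cursor = 1, 0, 10_000
    for unit in units:
        if placed_on_chrom >= config.genes_per_chrom:
            chrom_idx += 1
            placed_on_chrom, cursor = 0, 10_000
        chrom = f"chr{chrom_idx}"
        if len(unit) == 2:
            lnc, mrna = unit
            gap = int(rng.integers(0, 10_000))
            gaps[(lnc, mrna)] = gap
            start_l = cursor
            end_l = start_l + length_of[lnc]
            start_m = end_l + gap
            end_m = start_m + length_of[mrna]
            genes.append(GeneModel(lnc, chrom, start_l, end_l,
                                   "+" if rng.random() < 0.5 else "-",
                                   "lncRNA", length_of[lnc]))
            genes.append(GeneModel(mrna, chrom, start_m, end_m,
                                   "+" if rng.random() < 0.5 else "-",
                                   "mRNA", length_of[mrna]))
            cursor = end_m + config.intergenic_spacing
            placed_on_chrom += 2
        else:
            (g,) = unit
            start = cursor
            end = start + length_of[g]
            genes.append(GeneModel(g, chrom, start, end,
                                   "+" if rng.random() < 0.5 else "-",
                                   "lncRNA" if g.startswith("lnc") else "mRNA",
                                   length_of[g]))
            cursor = end + config.intergenic_spacing
            placed_on_chrom += 1
        if config.chrom_length_bp is not None and cursor > config.chrom_length_bp:
            raise ValidationError(
                f"placement exceeds chrom_length_bp={config.chrom_length_bp} "
                f"on {chrom}; too many genes for the chromosome length"
            )
    for lnc, mrna in zip(anchor_lncs, anchor_mrnas):
        truth.cis_pairs.append({"lnc": lnc, "mrna": mrna, "gap_bp": gaps[(lnc, mrna)]})
    for lnc, mrna in zip(cis_lncs, cis_mrnas):
        truth.cis_pairs.append({"lnc": lnc, "mrna": mrna, "gap_bp": gaps[(lnc, mrna)]})

    # ---- sequences: i.i.d. uniform ACGT, then plant complementary motifs
    sequences = {g: _random_seq(rng, length_of[g]) for g in lnc_ids + mrna_ids}

    def _plant_motif(lnc: str, mrna: str, motif_len: int) -> dict:
        mseq = sequences[mrna]
        m_start = int(rng.integers(0, len(mseq) - motif_len + 1))
        segment = mseq[m_start:m_start + motif_len]
        motif = segment.translate(_RC)[::-1]
        lseq = sequences[lnc]
        l_start = int(rng.integers(0, len(lseq) - motif_len + 1))
        sequences[lnc] = lseq[:l_start] + motif + lseq[l_start + motif_len:]
        return {"lnc": lnc, "mrna": mrna, "lnc_motif_start": l_start,
                "mrna_segment_start": m_start, "motif_len": motif_len}

    for lnc, mrna in zip(anchor_lncs, anchor_mrnas):
        truth.trans_pairs.append(_plant_motif(lnc, mrna, config.trans_motif_len))
    for lnc, mrna in zip(trans_lncs, trans_mrnas):
        truth.trans_pairs.append(_plant_motif(lnc, mrna, config.trans_motif_len))
    for lnc, mrna in zip(decoy_lncs, decoy_mrnas):
        truth.decoy_trans_pairs.append(_plant_motif(lnc, mrna, config.decoy_motif_len))

    order = {g: i for i, g in enumerate(lnc_ids + mrna_ids)}
    genes.sort(key=lambda g: order[g.gene_id])
    return genes, sequences, truth


def _nb_params(mean: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """scipy (r, p) parameterization for NB with variance mu + alpha mu^2."""
    r = np.full_like(mean, 1.0 / alpha)
    p = r / (r + mean)
    return r, p


def simulate_counts(
    config: SimConfig,
    genes: list[GeneModel],
    truth: GroundTruth,
) -> CountMatrix:
    """Draw the count matrix for the planted design.

    counts[g, j] ~ NB(mean = s_j * mu_g * 2^(+-log2fc if planted DE and j
    is a case sample) * 2^(loading * f_j if g is in a correlation block),
    variance = mean + alpha * mean^2), with size factors s_j log-uniform
    over ``size_factor_range`` and f_j a standard normal latent factor
    shared within each block (a lognormal factor on the count scale).
    Anchor-pair genes share a Gaussian copula on the NB noise so their
    expression is tightly correlated beyond the group effect.
    """
    rng = config.streams()["counts"]
    n = config.n_control + config.n_case
    sample_ids = [f"ctrl_{i + 1}" for i in range(config.n_control)] + \
                 [f"case_{i + 1}" for i in range(config.n_case)]
    conditions = ["control"] * config.n_control + ["case"] * config.n_case
    is_case = np.array([c == "case" for c in conditions])

    lo, hi = config.size_factor_range
    size_factors = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))

    block_of: dict[str, tuple[int, float]] = {}
    for b_idx, block in enumerate(truth.corr_blocks):
        for g in block["members"]:
            block_of[g] = (b_idx, block["loading_log2"])
    block_factors = rng.standard_normal((len(truth.corr_blocks), n))

    lo_m, hi_m = config.base_mean_range
    base_means = {}
    for g in genes:
        if g.gene_id in block_of:
            base_means[g.gene_id] = config.corr_block_mean
        else:
            base_means[g.gene_id] = float(np.exp(rng.uniform(np.log(lo_m), np.log(hi_m))))

    anchor_genes = {p["lnc"] for p in truth.anchor_pairs} | \
                   {p["mrna"] for p in truth.anchor_pairs}
    alpha = config.dispersion
    mat = np.zeros((len(genes), n), dtype=np.int64)
    for gi, g in enumerate(genes):
        mu = base_means[g.gene_id] * size_factors
        direction = truth.de_genes.get(g.gene_id)
        if direction is not None:
            shift = 2.0 ** (config.planted_log2fc if direction == "up"
                            else -config.planted_log2fc)
            mu = np.where(is_case, mu * shift, mu)
        if g.gene_id in block_of:
            b_idx, loading = block_of[g.gene_id]
            mu = mu * 2.0 ** (loading * block_factors[b_idx])
        if g.gene_id in anchor_genes:
            continue  # drawn below, coupled within each pair
        if alpha > 0:
            r, p = _nb_params(mu, alpha)
            mat[gi] = rng.negative_binomial(r, p)
        else:
            mat[gi] = rng.poisson(mu)

    gene_index = {g.gene_id: i for i, g in enumerate(genes)}
    rho = config.anchor_noise_corr
    for pair in truth.anchor_pairs:
        z_shared = rng.standard_normal(n)
        for gid in (pair["lnc"], pair["mrna"]):
            gi = gene_index[gid]
            g = genes[gi]
            mu = base_means[gid] * size_factors
            direction = truth.de_genes[gid]
            shift = 2.0 ** (config.planted_log2fc if direction == "up"
                            else -config.planted_log2fc)
            mu = np.where(is_case, mu * shift, mu)
            z = rho * z_shared + np.sqrt(1 - rho**2) * rng.standard_normal(n)
            u = stats.norm.cdf(z)
            if alpha > 0:
                r, p = _nb_params(mu, alpha)
                mat[gi] = stats.nbinom.ppf(u, r, p).astype(np.int64)
            else:
                mat[gi] = stats.poisson.ppf(u, mu).astype(np.int64)

    counts = pd.DataFrame(mat, index=[g.gene_id for g in genes], columns=sample_ids)
    counts.index.name = "gene_id"
    # true mapped-read totals (millions): depth scales with the size factor,
    # so RPKM normalization is not distorted by a few extreme genes
    nominal_depth = sum(base_means.values())
    mapped = [float(s * nominal_depth / 1e6) for s in size_factors]
    samples = SampleTable(sample_ids=sample_ids, conditions=conditions,
                          mapped_reads_millions=mapped)
    return CountMatrix(counts=counts, samples=samples)


def simulate_qpcr(
    fold_changes: dict[str, float],
    n_reps: int = 8,
    seed: int = 1729,
    noise_sd: float = 0.15,
    reference_ct: float = 15.0,
    baseline_ct: float = 25.0,
) -> pd.DataFrame:
    """Simulate a Ct table for the given per-gene fold changes.

    The reference gene has constant Ct plus Gaussian noise (sigma in
    cycles); each target's case-sample Ct is shifted by -log2(fold change)
    relative to its control baseline, so a perfect 2^-ddCt analysis
    recovers the planted fold change exactly at zero noise.
    """
    for gene, fc in fold_changes.items():
        if fc <= 0:
            raise ValidationError(f"non-positive fold change for {gene!r}")
    rng = np.random.default_rng(seed)
    rows = []
    sample_conditions = [("control", f"qctrl_{i + 1}") for i in range(n_reps)] + \
                        [("case", f"qcase_{i + 1}") for i in range(n_reps)]
    for gene in sorted(fold_changes):
        fc = fold_changes[gene]
        for condition, sample_id in sample_conditions:
            ct_target = baseline_ct
            if condition == "case":
                ct_target -= np.log2(fc)
            rows.append(
                {
                    "sample_id": sample_id,
                    "condition": condition,
                    "target_gene": gene,
                    "ct_target": ct_target + rng.normal(0.0, noise_sd) if noise_sd > 0
                    else ct_target,
                    "ct_reference": reference_ct + rng.normal(0.0, noise_sd)
                    if noise_sd > 0 else reference_ct,
                }
            )
    return pd.DataFrame(rows)
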