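"""Cis and trans prediction of lncRNA-associated protein-coding genes.

*Cis*: an mRNA is a candidate target of a lncRNA when the two gene spans lie
on the same chromosome with a genomic gap below 10 kb (overlap counts as
gap 0; strand is ignored).

*Trans*: a candidate when the lncRNA sequence is complementary to the mRNA.
Complementarity is scored as the best Smith-Waterman local alignment between
the lncRNA and the reverse complement of the mRNA (match +2, mismatch -3,
linear gap -5), which is equivalent to scoring antiparallel base pairing.
Two filters are applied, both strict: a Karlin-Altschul E-value
``e = K * m * n * exp(-lambda * S)`` calibrated on shuffled sequence pairs
must fall below 1e-5, and an additive duplex energy G (G:C -3, A:T -2,
G:U wobble -1, mismatches and gaps +1 each) must fall below -20.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from scipy import stats

from .models import CisPair, GeneModel, TransHit, ValidationError


@dataclass(frozen=True)
class AlignmentScoring:
    match: float = 2.0
    mismatch: float = -3.0
    gap: float = -5.0


@dataclass(frozen=True)
class EnergyModel:
    """Additive per-column duplex energies on the trans G scale."""

    gc: float = -3.0
    at: float = -2.0
    wobble: float = -1.0
    penalty: float = 1.0  # per mismatch or gap column
    wobble_enabled: bool = True


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner(mode="local")
    al.match_score = scoring.match
    al.mismatch_score = scoring.mismatch
    al.open_gap_score = scoring.gap
    al.extend_gap_score = scoring.gap
    return al


# -- cis --------------------------------------------------------------------

def gene_gap(a: GeneModel, b: GeneModel) -> int | None:
    """Genomic gap between two gene spans; 0 when they overlap; None when on
    different chromosomes."""
    if a.chrom != b.chrom:
        return None
    return max(0, b.start - a.end, a.start - b.end)


def tss_distance(a: GeneModel, b: GeneModel) -> int | None:
    """Strand-aware transcription start site distance (alternative metric)."""
    if a.chrom != b.chrom:
        return None
    tss_a = a.start if a.strand == "+" else a.end - 1
    tss_b = b.start if b.strand == "+" else b.end - 1
    return abs(tss_a - tss_b)


def find_cis_targets(
    de_lncs: list[GeneModel],
    mrnas: list[GeneModel],
    max_gap_bp: int = 10_000,
    metric: str = "gap",
) -> list[CisPair]:
    """All (lncRNA, mRNA) pairs with distance strictly below ``max_gap_bp``.

    ``metric='gap'`` (default) measures the gap between gene spans;
    ``metric='tss'`` the distance between transcription start sites.
    """
    if metric not in ("gap", "tss"):
        raise ValueError("metric must be 'gap' or 'tss'")
    dist_fn = gene_gap if metric == "gap" else tss_distance
    pairs: list[CisPair] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in mrnas:
        by_chrom.setdefault(m.chrom, []).append(m)
    for lnc in de_lncs:
        for m in by_chrom.get(lnc.chrom, []):
            d = dist_fn(lnc, m)
            if d is not None and d < max_gap_bp:
                pairs.append(CisPair(lnc_id=lnc.gene_id, mrna_id=m.gene_id, gap_bp=d))
    pairs.sort(key=lambda p: (p.lnc_id, p.mrna_id))
    return pairs


# -- trans ------------------------------------------------------------------

def complement_align(
    lnc_seq: str,
    mrna_seq: str,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> tuple[float, tuple[int, int, int, int] | None, list[tuple[str, str]]]:
    """Best local alignment of the lncRNA against the reverse complement of
    the mRNA.

    Returns ``(score, span, columns)`` where ``span`` is
    (lnc_start, lnc_end, mrna_start, mrna_end) in each molecule's own
    coordinates and ``columns`` lists the aligned columns as character pairs
    ``(lnc_base, rc_mrna_base)`` with ``'-'`` for gaps.  Empty input gives
    score 0 and an empty alignment.
    """
    if not lnc_seq or not mrna_seq:
        return 0.0, None, []
    rc = reverse_complement(mrna_seq)
    al = _aligner(scoring)
    if al.score(lnc_seq, rc) <= 0:
        return 0.0, None, []
    best = al.align(lnc_seq, rc)[0]
    score = float(best.score)
    blocks_a, blocks_b = best.aligned
    if len(blocks_a) == 0:
        return 0.0, None, []
    columns: list[tuple[str, str]] = []
    prev_a_end = prev_b_end = None
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        if prev_a_end is not None:
            for i in range(prev_a_end, a0):
                columns.append((lnc_seq[i], "-"))
            for j in range(prev_b_end, b0):
                columns.append(("-", rc[j]))
        for i, j in zip(range(a0, a1), range(b0, b1)):
            columns.append((lnc_seq[i], rc[j]))
        prev_a_end, prev_b_end = a1, b1
    a_start, a_end = int(blocks_a[0][0]), int(blocks_a[-1][1])
    b_start, b_end = int(blocks_b[0][0]), int(blocks_b[-1][1])
    n = len(mrna_seq)
    span = (a_start, a_end, n - b_end, n - b_start)  # map rc coords back to mRNA
    return score, span, columns


def hybrid_energy(
    columns: list[tuple[str, str]],
    model: EnergyModel = EnergyModel(),
) -> float:
    """Additive duplex energy of an alignment's columns.

    Aligned identical characters (in reverse-complement space) are
    complementary base pairs: G or C -> G:C pair, A or T -> A:T pair.
    G:U wobble pairs appear in reverse-complement space as (G, A) or (T, C)
    lncRNA/rc-mRNA character pairs.  Every mismatch or gap column costs the
    same positive penalty.  An empty alignment has energy 0.
    """
    g = 0.0
    for x, y in columns:
        if x == "-" or y == "-":
            g += model.penalty
        elif x == y:
            g += model.gc if x in "GC" else model.at
        elif model.wobble_enabled and (x, y) in (("G", "A"), ("T", "C")):
            g += model.wobble
        else:
            g += model.penalty
    return g


def evalue(score: float, m: float, n: float, lam: float, K: float) -> float:
    """Karlin-Altschul expected hit count, e = K m n exp(-lambda S)."""
    return float(K * m * n * np.exp(-lam * score))


@dataclass(frozen=True)
class EvalueCalibration:
    lam: float
    K: float
    m: float  # mean query (lncRNA) length of the calibration pool
    n: float  # mean subject (mRNA) length


def calibrate_evalue(
    score_samples: np.ndarray | list[float],
    m: float,
    n: float,
) -> EvalueCalibration:
    """Fit the Gumbel tail of shuffled-pair local alignment scores.

    Maximum-likelihood Gumbel fit gives location mu and scale beta;
    lambda = 1/beta and K = exp(lambda mu) / (m n), so that
    ``K m n exp(-lambda S)`` approximates the expected number of chance hits
    scoring at least S.
    """
    scores = np.asarray(score_samples, dtype=float)
    if scores.size < 500:
        raise ValidationError("need >= 500 shuffled-pair scores for calibration")
    if np.std(scores) == 0:
        raise ValidationError("degenerate (constant) score distribution")
    mu, beta = stats.gumbel_r.fit(scores)
    lam = 1.0 / beta
    K = float(np.exp(lam * mu) / (m * n))
    return EvalueCalibration(lam=float(lam), K=K, m=float(m), n=float(n))


def calibration_from_pool(
    lnc_seqs: dict[str, str],
    mrna_seqs: dict[str, str],
    n_samples: int = 500,
    seed: int = 1729,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> EvalueCalibration:
    """Calibrate on dinucleotide-free shuffles of random pairs from the input pool."""
    rng = np.random.default_rng(seed)
    lnc_pool = sorted(lnc_seqs.values(), key=len)
    mrna_pool = sorted(mrna_seqs.values(), key=len)
    if not lnc_pool or not mrna_pool:
        raise ValidationError("empty sequence pool for E-value calibration")
    al = _aligner(scoring)
    scores = np.empty(n_samples)
    for i in range(n_samples):
        a = list(lnc_pool[rng.integers(len(lnc_pool))])
        b = list(mrna_pool[rng.integers(len(mrna_pool))])
        rng.shuffle(a)
        rng.shuffle(b)
        scores[i] = al.score("".join(a), reverse_complement("".join(b)))
    m = float(np.mean([len(s) for s in lnc_seqs.values()]))
    n = float(np.mean([len(s) for s in mrna_seqs.values()]))
    return calibrate_evalue(scores, m, n)


def find_trans_targets(
    lnc_seqs: dict[str, str],
    mrna_seqs: dict[str, str],
    evalue_threshold: float = 1e-5,
    energy_threshold: float = -20.0,
    calibration: EvalueCalibration | None = None,
    seed: int = 1729,
    scoring: AlignmentScoring = AlignmentScoring(),
    energy_model: EnergyModel = EnergyModel(),
) -> list[TransHit]:
    """Score every (lncRNA, mRNA) pair; retain hits with e < threshold and
    G < threshold (both strict), sorted by ascending E-value.

    A missing/empty sequence raises, naming the gene.  When no calibration
    is supplied one is computed from shuffles of the input pool (seeded).
    """
    for name, seqs in (("lncRNA", lnc_seqs), ("mRNA", mrna_seqs)):
        for gid, seq in seqs.items():
            if not seq:
                raise ValidationError(f"missing sequence for {name} {gid!r}")
    if not lnc_seqs or not mrna_seqs:
        return []
    if calibration is None:
        calibration = calibration_from_pool(lnc_seqs, mrna_seqs, seed=seed, scoring=scoring)
    al = _aligner(scoring)
    rc_cache = {mid: reverse_complement(seq) for mid, seq in mrna_seqs.items()}
    hits: list[TransHit] = []
    for lid in sorted(lnc_seqs):
        lseq = lnc_seqs[lid]
        for mid in sorted(mrna_seqs):
            s = float(al.score(lseq, rc_cache[mid]))
            e = evalue(s, len(lseq), len(mrna_seqs[mid]), calibration.lam, calibration.K)
            if e >= evalue_threshold:
                continue
            score, span, columns = complement_align(lseq, mrna_seqs[mid], scoring)
            g = hybrid_energy(columns, energy_model)
            if g < energy_threshold:
                hits.append(
                    TransHit(
                        lnc_id=lid, mrna_id=mid, score=score,
                        energy_G=g, evalue=e, alignment=span,
                    )
                )
    for h in hits:  # self-consistency of the advertised thresholds
        assert h.evalue < evalue_threshold and h.energy_G < energy_threshold
    hits.sort(key=lambda h: (h.evalue, h.lnc_id, h.mrna_id))
    return hits


# -- intersection -----------------------------------------------------------

def intersect_cis_trans(cis: list[CisPair], trans: list[TransHit]) -> dict:
    """lncRNAs, target genes and (lnc, target) connections common to both
    analyses, with counts."""
    cis_conn = {(p.lnc_id, p.mrna_id) for p in cis}
    trans_conn = {(h.lnc_id, h.mrna_id) for h in trans}
    lnc_common = {l for l, _ in cis_conn} & {l for l, _ in trans_conn}
    target_common = {m for _, m in cis_conn} & {m for _, m in trans_conn}
    conn_common = cis_conn & trans_conn
    return {
        "lncRNAs": sorted(lnc_common),
        "targets": sorted(target_common),
        "connections": sorted(conn_common),
        "n_lncRNAs": len(lnc_common),
        "n_targets": len(target_common),
        "n_connections": len(conn_common),
    }
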