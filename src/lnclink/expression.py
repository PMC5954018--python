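"""Quantification and negative-binomial differential expression.

The model follows the classic count-based DE recipe for a two-group design
(control vs case, here 3 + 3 replicates):

* RPKM = total exon reads / (mapped reads in millions x exon length in kb)
  for reporting and co-expression analysis;
* median-of-ratios size factors for normalization;
* per-gene method-of-moments negative-binomial dispersion alpha with
  variance mu + alpha * mu^2;
* a Wald test on log2 fold change with a delta-method standard error;
* Benjamini-Hochberg adjustment, and the selection rule fold change > 2
  and padj < 0.05 (both strict).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import CountMatrix, DEResult, GeneModel, ValidationError

logger = logging.getLogger(__name__)

LOG2FC_PSEUDOCOUNT = 0.5


def compute_rpkm(counts: CountMatrix, genes: list[GeneModel]) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads.

    ``mapped_reads_millions`` is taken from the sample table when present,
    otherwise computed as the column sum / 1e6.
    """
    lengths = {g.gene_id: g.exon_length_bp for g in genes}
    missing = [gid for gid in counts.gene_ids if gid not in lengths]
    if missing:
        raise ValidationError(f"no exon length for genes: {missing[:5]}")
    if counts.samples.mapped_reads_millions is not None:
        mapped = np.asarray(counts.samples.mapped_reads_millions, dtype=float)
    else:
        mapped = counts.counts.sum(axis=0).to_numpy(dtype=float) / 1e6
    if (mapped <= 0).any():
        raise ValidationError("zero mapped reads in at least one sample")
    len_kb = np.array([lengths[g] / 1000.0 for g in counts.gene_ids])
    rpkm = counts.counts.to_numpy(dtype=float) / (mapped[None, :] * len_kb[:, None])
    return pd.DataFrame(rpkm, index=counts.counts.index, columns=counts.counts.columns)


def estimate_size_factors(counts: CountMatrix | pd.DataFrame) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each gene with positive counts in all samples, the ratio of each
    sample's count to the gene's geometric mean is formed; the per-sample
    median of those ratios is the size factor.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    mat = df.to_numpy(dtype=float)
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any():
        raise ValidationError(
            "no gene has positive counts in every sample; "
            "add a pseudocount or filter samples"
        )
    sub = mat[all_pos]
    log_geomean = np.mean(np.log(sub), axis=1)
    ratios = np.log(sub) - log_geomean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean 1
    return factors


def estimate_dispersion(
    counts: CountMatrix,
    size_factors: np.ndarray,
) -> np.ndarray:
    """Per-gene NB dispersion alpha (variance = mu + alpha mu^2).

    Method-of-moments on within-condition normalized counts,
    alpha = max(0, (v - m) / m^2), averaged across the two conditions.
    Genes where the estimate is undefined in both conditions (all-zero)
    get the global fallback, the median of the positive per-gene values.
    """
    norm = counts.counts.to_numpy(dtype=float) / size_factors[None, :]
    conditions = np.asarray(counts.samples.conditions)
    per_cond: list[np.ndarray] = []
    for cond in ("control", "case"):
        sub = norm[:, conditions == cond]
        if sub.shape[1] < 2:
            raise ValidationError(f"need >= 2 replicates in condition {cond!r}")
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha = np.where(m > 0, np.maximum(0.0, (v - m) / m**2), np.nan)
        per_cond.append(alpha)
    stacked = np.vstack(per_cond)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        alpha = np.nanmean(stacked, axis=0)
    positive = alpha[np.isfinite(alpha) & (alpha > 0)]
    fallback = float(np.median(positive)) if positive.size else 0.0
    alpha = np.where(np.isfinite(alpha), alpha, fallback)
    return alpha


def moderate_dispersion(alpha: np.ndarray) -> np.ndarray:
    """Conservative per-gene dispersion: elementwise max with the global
    median of positive estimates.

    With 3 replicates per group the raw method-of-moments estimate is very
    noisy and frequently zero, which makes the Wald test anti-conservative;
    flooring each gene at the global median restores near-nominal type-I
    error while keeping genuinely high-dispersion genes conservative.
    """
    positive = alpha[np.isfinite(alpha) & (alpha > 0)]
    if positive.size == 0:
        return alpha.copy()
    return np.maximum(alpha, float(np.median(positive)))


def de_test(
    counts: CountMatrix,
    size_factors: np.ndarray,
    dispersions: np.ndarray,
    pseudocount: float = LOG2FC_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Wald test of case vs control on normalized NB counts.

    log2fc = log2((mean_case + c) / (mean_control + c)); the standard error
    of log2fc comes from the delta method applied to the NB variance of each
    group mean, Var(mean) = (1/n^2) sum_j (mu / s_j + alpha mu^2); the
    two-sided p is a normal tail on z = log2fc / SE.
    """
    conditions = np.asarray(counts.samples.conditions)
    for cond in ("control", "case"):
        if (conditions == cond).sum() < 2:
            raise ValidationError(f"single-replicate group {cond!r}: variance undefined")
    norm = counts.counts.to_numpy(dtype=float) / size_factors[None, :]
    out = {}
    var_terms = {}
    for cond in ("control", "case"):
        mask = conditions == cond
        sub = norm[:, mask]
        n = mask.sum()
        mean = sub.mean(axis=1)
        s = size_factors[mask]
        mu = mean[:, None]
        var_mean = (mu / s[None, :] + dispersions[:, None] * mu**2).sum(axis=1) / n**2
        out[cond] = mean
        var_terms[cond] = var_mean
    c = pseudocount
    log2fc = np.log2((out["case"] + c) / (out["control"] + c))
    ln2sq = np.log(2.0) ** 2
    se2 = (
        var_terms["case"] / ((out["case"] + c) ** 2 * ln2sq)
        + var_terms["control"] / ((out["control"] + c) ** 2 * ln2sq)
    )
    se = np.sqrt(se2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.minimum(p, 1.0)
    return pd.DataFrame(
        {
            "base_mean_control": out["control"],
            "base_mean_case": out["case"],
            "log2fc": log2fc,
            "se": se,
            "z": z,
            "p": p,
        },
        index=counts.counts.index,
    )


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    _, padj, _, _ = multipletests(p, method="fdr_bh")
    return padj


def select_significant(
    de_table: pd.DataFrame,
    biotypes: dict[str, str] | None = None,
    fold_change: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Apply the selection rule |log2fc| > log2(fold_change) and padj < alpha.

    Both inequalities are strict.  Returns a copy of the table with
    ``padj`` (computed here if absent), ``significant`` and ``direction``
    columns, plus a ``biotype`` column when a mapping is given.
    """
    if fold_change <= 0 or not (0 < alpha < 1):
        raise ValidationError("fold_change must be > 0 and alpha in (0, 1)")
    lfc_thr = np.log2(fold_change)
    df = de_table.copy()
    if "padj" not in df.columns:
        df["padj"] = bh_adjust(df["p"].to_numpy())
    sig = (np.abs(df["log2fc"]) > lfc_thr) & (df["padj"] < alpha)
    df["significant"] = sig
    df["direction"] = np.where(
        sig & (df["log2fc"] > 0), "up", np.where(sig & (df["log2fc"] < 0), "down", "none")
    )
    if biotypes is not None:
        df["biotype"] = [biotypes.get(g, "") for g in df.index]
    return df


def de_summary(selected: pd.DataFrame) -> dict:
    """Counts of significant genes per direction and (if present) biotype."""
    out = {
        "n_genes": int(len(selected)),
        "n_significant": int(selected["significant"].sum()),
        "n_up": int((selected["direction"] == "up").sum()),
        "n_down": int((selected["direction"] == "down").sum()),
    }
    if "biotype" in selected.columns:
        for bt in ("lncRNA", "mRNA"):
            sub = selected[selected["biotype"] == bt]
            out[f"n_{bt}_significant"] = int(sub["significant"].sum())
            out[f"n_{bt}_up"] = int((sub["direction"] == "up").sum())
            out[f"n_{bt}_down"] = int((sub["direction"] == "down").sum())
    return out


def differential_expression(
    counts: CountMatrix,
    biotypes: dict[str, str] | None = None,
    fold_change: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full DE chain: size factors -> dispersions -> Wald test -> BH -> selection."""
    size_factors = estimate_size_factors(counts)
    dispersions = moderate_dispersion(estimate_dispersion(counts, size_factors))
    table = de_test(counts, size_factors, dispersions)
    table["padj"] = bh_adjust(table["p"].to_numpy())
    return select_significant(table, biotypes=biotypes, fold_change=fold_change, alpha=alpha)


def results_from_table(table: pd.DataFrame) -> list[DEResult]:
    return [
        DEResult(
            gene_id=str(gid),
            biotype=str(row.get("biotype", "")),
            base_mean_control=float(row["base_mean_control"]),
            base_mean_case=float(row["base_mean_case"]),
            log2fc=float(row["log2fc"]),
            p=float(row["p"]),
            padj=float(row["padj"]),
            significant=bool(row["significant"]),
            direction=str(row["direction"]),
        )
        for gid, row in table.iterrows()
    ]


def volcano_coords(de_table: pd.DataFrame) -> pd.DataFrame:
    """(x, y) per gene for a volcano plot: x = log2fc, y = -log10 padj."""
    padj = np.clip(de_table["padj"].to_numpy(dtype=float), 1e-300, 1.0)
    return pd.DataFrame(
        {"x": de_table["log2fc"].to_numpy(), "y": -np.log10(padj)}, index=de_table.index
    )


# -- hierarchical clustering ------------------------------------------------

def _correlation_distance(mat: np.ndarray) -> np.ndarray:
    """d = 1 - Pearson r between rows; zero-variance rows get r = 0 (d = 1)."""
    n = mat.shape[0]
    sd = mat.std(axis=1)
    zero_var = sd == 0
    if zero_var.any():
        logger.warning("%d zero-variance items in clustering; correlations set to 0",
                       int(zero_var.sum()))
    centered = mat - mat.mean(axis=1, keepdims=True)
    denom = np.outer(sd, sd) * mat.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = centered @ centered.T / denom
    corr[zero_var, :] = 0.0
    corr[:, zero_var] = 0.0
    np.fill_diagonal(corr, 1.0)
    d = 1.0 - corr
    d[np.arange(n), np.arange(n)] = 0.0
    return d


def cluster_expression(
    expression: pd.DataFrame,
    axis: str = "samples",
    log_transform: bool = True,
) -> list[tuple[tuple[str, ...], tuple[str, ...], float]]:
    """Average-linkage agglomeration on 1 - Pearson r.

    Returns the merge list: each entry is ``(members_a, members_b, height)``
    with members as sorted id tuples.  Ties are broken by the
    lexicographically smallest (members_a, members_b) pair, so the result is
    deterministic.  ``axis='samples'`` clusters columns, ``'genes'`` rows.
    """
    if axis == "samples":
        mat = expression.to_numpy(dtype=float).T
        ids = [str(c) for c in expression.columns]
    elif axis == "genes":
        mat = expression.to_numpy(dtype=float)
        ids = [str(i) for i in expression.index]
    else:
        raise ValueError("axis must be 'samples' or 'genes'")
    if len(ids) < 2:
        raise ValidationError("need at least 2 items to cluster")
    if log_transform:
        mat = np.log2(mat + 1.0)
    dist = _correlation_distance(mat)

    clusters: dict[tuple[str, ...], list[int]] = {(i,): [k] for k, i in enumerate(ids)}
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]] = []
    while len(clusters) > 1:
        best: tuple[float, tuple[str, ...], tuple[str, ...]] | None = None
        keys = sorted(clusters)
        for a_i in range(len(keys)):
            for b_i in range(a_i + 1, len(keys)):
                a, b = keys[a_i], keys[b_i]
                # average linkage: mean pairwise leaf distance
                h = float(np.mean(dist[np.ix_(clusters[a], clusters[b])]))
                cand = (h, a, b)
                if best is None or cand < best:
                    best = cand
        h, a, b = best
        merged = tuple(sorted(a + b))
        clusters[merged] = clusters.pop(a) + clusters.pop(b)
        merges.append((a, b, h))
    return merges


def top_branches(merges) -> tuple[frozenset[str], frozenset[str]]:
    """The two member sets joined by the final (root) merge."""
    a, b, _h = merges[-1]
    return frozenset(a), frozenset(b)
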