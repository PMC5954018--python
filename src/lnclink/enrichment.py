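"""Hypergeometric over-representation analysis against GMT gene sets.

A local stand-in for web-service GO/KEGG/chemicals enrichment: for each gene
set, the upper tail P(X >= k) of a hypergeometric draw (universe N, set K,
query n, overlap k) is computed in log space, followed by Benjamini-Hochberg
adjustment across sets.  Only over-representation (one-sided) is tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .expression import bh_adjust
from .models import GeneSetCollection, ValidationError

SET_SIZE_MIN = 3
SET_SIZE_MAX = 2000


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exact, log-space."""
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValidationError(
            f"inconsistent hypergeometric arguments k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass
class EnrichmentResult:
    set_id: str
    description: str
    k: int
    K: int
    n: int
    N: int
    p: float
    padj: float
    up_fraction: float
    down_fraction: float
    overlap_genes: tuple[str, ...]


def enrich(
    query_genes: dict[str, str] | set[str],
    gene_sets: GeneSetCollection,
    universe: set[str],
    set_size_bounds: tuple[int, int] = (SET_SIZE_MIN, SET_SIZE_MAX),
) -> pd.DataFrame:
    """One hypergeometric test per gene set, BH-adjusted across sets.

    ``query_genes`` may carry DE directions (dict gene -> up|down), from
    which the up/down fractions of each overlap are computed.  Set members
    are filtered to the universe, and sets outside the size bounds are
    skipped.  Results are sorted by ascending p.
    """
    if not universe:
        raise ValidationError("empty universe")
    directions = query_genes if isinstance(query_genes, dict) else {}
    query = set(query_genes) & set(universe)
    N = len(universe)
    n = len(query)
    lo, hi = set_size_bounds
    rows = []
    for gs in gene_sets:
        members = gs.members & universe
        K = len(members)
        if not (lo <= K <= hi):
            continue
        overlap = sorted(members & query)
        k = len(overlap)
        p = hypergeom_upper_tail(k, K, n, N)
        ups = sum(1 for g in overlap if directions.get(g) == "up")
        downs = sum(1 for g in overlap if directions.get(g) == "down")
        rows.append(
            {
                "set_id": gs.set_id,
                "description": gs.description,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": p,
                "up_fraction": ups / k if k else 0.0,
                "down_fraction": downs / k if k else 0.0,
                "overlap_genes": ",".join(overlap),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["set_id", "description", "k", "K", "n", "N", "p",
                 "up_fraction", "down_fraction", "overlap_genes"],
    )
    if len(df):
        df["padj"] = bh_adjust(df["p"].to_numpy())
        df = df.sort_values(["p", "set_id"], kind="mergesort").reset_index(drop=True)
    else:
        df["padj"] = pd.Series(dtype=float)
    return df
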