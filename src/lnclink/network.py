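"""Coding/non-coding co-expression network and cross-species overlap.

Edges connect a DE lncRNA to a predicted target gene when the Pearson
correlation of their log2(RPKM + 1) profiles across all samples exceeds the
threshold (default signed r > 0.95, strict; absolute-value mode available).
Node colour semantics follow the usual convention: up-regulated genes red,
down-regulated green, encoded here as a ``direction`` attribute.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .models import OrthologMap, ValidationError

logger = logging.getLogger(__name__)


def filter_targets_by_de(predicted_targets: set[str], de_mrna_ids: set[str]) -> set[str]:
    """Restrict predicted target genes to those significantly DE."""
    return set(predicted_targets) & set(de_mrna_ids)


def pearson_r(x, y) -> float:
    """Product-moment correlation; zero-variance input gives r = 0 (warned)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("vectors differ in length")
    if x.size < 3:
        raise ValidationError("need >= 3 observations")
    if x.std() == 0 or y.std() == 0:
        logger.warning("zero-variance vector in pearson_r; returning r = 0")
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def build_coexpression_network(
    lnc_ids: set[str],
    target_ids: set[str],
    expression: pd.DataFrame,
    connections: list[tuple[str, str]],
    directions: dict[str, str],
    threshold: float = 0.95,
    absolute: bool = False,
    keep_isolated: bool = False,
):
    """Build the lncRNA-target co-expression network.

    ``expression`` is RPKM (genes x samples); correlations are computed on
    log2(RPKM + 1).  Only the candidate ``connections`` (predicted
    lncRNA -> target links) are tested; an edge is kept iff r > threshold
    (or |r| > threshold with ``absolute=True``), strictly.

    Returns ``(nodes, edges, summary)``: nodes map id -> {kind, direction},
    edges are (lnc_id, target_id, r), and the degree summary reports the
    maximum number of targets per lncRNA and lncRNAs per target.
    """
    log_expr = np.log2(expression + 1.0)
    edges: list[tuple[str, str, float]] = []
    for lnc, tgt in sorted(set(connections)):
        if lnc not in lnc_ids or tgt not in target_ids:
            continue
        if lnc not in log_expr.index or tgt not in log_expr.index:
            raise ValidationError(f"no expression row for candidate pair ({lnc}, {tgt})")
        r = pearson_r(log_expr.loc[lnc], log_expr.loc[tgt])
        stat = abs(r) if absolute else r
        if stat > threshold:
            edges.append((lnc, tgt, r))
    nodes: dict[str, dict] = {}

    def _add_node(gid: str, kind: str) -> None:
        nodes[gid] = {"kind": kind, "direction": directions.get(gid, "")}

    if keep_isolated:
        for gid in sorted(lnc_ids):
            _add_node(gid, "lncRNA")
        for gid in sorted(target_ids):
            _add_node(gid, "mRNA")
    else:
        for lnc, tgt, _r in edges:
            _add_node(lnc, "lncRNA")
            _add_node(tgt, "mRNA")
    lnc_deg: dict[str, int] = {}
    tgt_deg: dict[str, int] = {}
    for lnc, tgt, _r in edges:
        lnc_deg[lnc] = lnc_deg.get(lnc, 0) + 1
        tgt_deg[tgt] = tgt_deg.get(tgt, 0) + 1
    summary = {
        "n_nodes": len(nodes),
        "n_edges": len(edges),
        "n_lncRNAs": sum(1 for n in nodes.values() if n["kind"] == "lncRNA"),
        "n_targets": sum(1 for n in nodes.values() if n["kind"] == "mRNA"),
        "max_targets_per_lncRNA": max(lnc_deg.values(), default=0),
        "max_lncRNAs_per_target": max(tgt_deg.values(), default=0),
    }
    return nodes, edges, summary


def cross_species_overlap(
    mouse_targets: dict[str, str],
    human_de_genes: set[str],
    ortholog_map: OrthologMap,
) -> pd.DataFrame:
    """Overlap mouse lncRNA-target genes with a human DE gene list.

    ``mouse_targets`` maps mouse gene id -> DE direction.  Mouse ids absent
    from the ortholog map are reported (``mapped`` False), never silently
    dropped.  Returns one row per mouse gene with its human ortholog and
    whether that ortholog is in the human DE set.
    """
    rows = []
    for mid in sorted(mouse_targets):
        hid = ortholog_map.get(mid)
        rows.append(
            {
                "mouse_gene_id": mid,
                "human_gene_id": hid if hid is not None else "",
                "mouse_direction": mouse_targets[mid],
                "mapped": hid is not None,
                "common": hid is not None and hid in human_de_genes,
            }
        )
    return pd.DataFrame(rows, columns=["mouse_gene_id", "human_gene_id",
                                       "mouse_direction", "mapped", "common"])
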