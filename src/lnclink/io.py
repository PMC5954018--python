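"""Readers and writers for the external formats the pipeline touches.

Formats: GTF2.2 / BED6+ (annotation), FASTA (sequences), TSV (counts,
samples, generic tables), Broad-dialect GMT (gene sets), SIF and GraphML
(networks).  Every writer has a matching reader and round-trips exactly.
"""

from __future__ import annotations

import re
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    CountMatrix,
    GeneModel,
    GeneSet,
    GeneSetCollection,
    OrthologMap,
    SampleTable,
    ValidationError,
    check_unique_gene_ids,
    normalize_sequence,
)


class ParseError(ValueError):
    """Malformed input file; message names the file and line."""


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_attrs(field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def read_annotation(path: str | Path, format: str = "gtf") -> list[GeneModel]:
    """Read gene models from GTF (1-based, closed) or BED6+ (0-based).

    GTF ``gene`` records carry ``gene_id``, ``biotype`` (or ``gene_biotype``)
    and optionally ``exon_length`` attributes; without the latter the exon
    length defaults to the genomic span (single-exon assumption).  The BED
    dialect is BED6 with biotype in column 7 and exon length in optional
    column 8.
    """
    path = Path(path)
    if format not in ("gtf", "bed"):
        raise ValueError(f"unsupported annotation format {format!r}")
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if format == "gtf":
                    if len(fields) < 9:
                        raise ParseError("expected 9 tab-separated fields")
                    chrom, _src, feature, start1, end1, _score, strand, _frame, attrs = fields[:9]
                    if feature != "gene":
                        continue
                    attrd = _parse_gtf_attrs(attrs)
                    if "gene_id" not in attrd:
                        raise ParseError("missing gene_id attribute")
                    biotype = attrd.get("biotype") or attrd.get("gene_biotype")
                    if biotype is None:
                        raise ParseError("missing biotype attribute")
                    start = int(start1) - 1  # GTF is 1-based inclusive
                    end = int(end1)
                    exon_length = int(attrd.get("exon_length", end - start))
                    gene_id = attrd["gene_id"]
                else:
                    if len(fields) < 7:
                        raise ParseError("expected >= 7 tab-separated fields (BED6+biotype)")
                    chrom, start_s, end_s, gene_id, _score, strand = fields[:6]
                    biotype = fields[6]
                    start, end = int(start_s), int(end_s)
                    exon_length = int(fields[7]) if len(fields) > 7 else end - start
                genes.append(
                    GeneModel(
                        gene_id=gene_id,
                        chrom=chrom,
                        start=start,
                        end=end,
                        strand=strand,
                        biotype=biotype,
                        exon_length_bp=exon_length,
                    )
                )
            except (ParseError, ValidationError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    check_unique_gene_ids(genes)
    return genes


def write_annotation(genes: list[GeneModel], path: str | Path, format: str = "gtf") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for g in genes:
            if format == "gtf":
                attrs = (
                    f'gene_id "{g.gene_id}"; biotype "{g.biotype}"; '
                    f'exon_length "{g.exon_length_bp}";'
                )
                fh.write(
                    f"{g.chrom}\tlnclink\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )
            elif format == "bed":
                fh.write(
                    f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}"
                    f"\t{g.biotype}\t{g.exon_length_bp}\n"
                )
            else:
                raise ValueError(f"unsupported annotation format {format!r}")


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> {gene_id: sequence}; header token before whitespace is the id,
    sequences uppercased with RNA U normalized to T."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ParseError(f"{path}: duplicate FASTA header {rec.id!r}")
        out[rec.id] = normalize_sequence(str(rec.seq), context=rec.id)
    return out


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=gene_id, description="") for gene_id, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_samples(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})
    for col in ("sample_id", "condition"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    mapped = None
    if "mapped_reads_millions" in df.columns and df["mapped_reads_millions"].notna().all():
        mapped = df["mapped_reads_millions"].astype(float).tolist()
    return SampleTable(
        sample_ids=df["sample_id"].tolist(),
        conditions=df["condition"].tolist(),
        mapped_reads_millions=mapped,
    )


def write_samples(samples: SampleTable, path: str | Path) -> None:
    samples.to_frame().to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path, samples: SampleTable) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        raise ParseError(f"{path}: non-numeric count value")
    if not np.allclose(vals, np.round(vals)):
        raise ParseError(f"{path}: non-integer count value")
    if (vals < 0).any():
        raise ParseError(f"{path}: negative count value")
    return CountMatrix(counts=df.astype(np.int64), samples=samples)


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    df = matrix.counts.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Broad-dialect GMT: set_id TAB description TAB member1 TAB member2 ..."""
    sets = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            sets.append(
                GeneSet(set_id=fields[0], description=fields[1], members=frozenset(fields[2:]))
            )
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            members = "\t".join(sorted(s.members))
            fh.write(f"{s.set_id}\t{s.description}\t{members}\n")


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """2-column TSV (mouse_gene_id, human_gene_id), header optional."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 tab-separated fields")
            if lineno == 1 and fields[0] in ("mouse_gene_id", "mouse_id"):
                continue
            if fields[0] in mapping and mapping[fields[0]] != fields[1]:
                raise ParseError(
                    f"{path}:{lineno}: mouse id {fields[0]!r} maps to multiple human ids"
                )
            mapping[fields[0]] = fields[1]
    return OrthologMap(mapping)


def read_table(path: str | Path, schema: dict[str, type]) -> pd.DataFrame:
    """Generic header-row TSV with required, typed columns."""
    df = pd.read_csv(path, sep="\t")
    for col, typ in schema.items():
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
        try:
            df[col] = df[col].astype(typ)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: column {col!r} not coercible to {typ}") from exc
    return df


# -- networks ---------------------------------------------------------------

def _check_network(nodes: dict[str, dict], edges: list[tuple[str, str, float]]) -> None:
    for u, v, _r in edges:
        if u not in nodes or v not in nodes:
            raise ValidationError(f"dangling edge ({u}, {v})")


def write_network(
    nodes: dict[str, dict],
    edges: list[tuple[str, str, float]],
    path: str | Path,
    format: str = "sif",
) -> None:
    """Export a co-expression network.

    ``nodes`` maps id -> attributes (``kind``: lncRNA|mRNA, ``direction``:
    up|down); edges are ``(source, target, r)``.  SIF gets a ``.attrs.tsv``
    sidecar with node attributes; GraphML stores them inline.
    """
    _check_network(nodes, edges)
    path = Path(path)
    if format == "sif":
        with open(path, "w") as fh:
            for u, v, _r in edges:
                fh.write(f"{u}\tcoexp\t{v}\n")
        sidecar = path.with_suffix(path.suffix + ".attrs.tsv")
        with open(sidecar, "w") as fh:
            fh.write("node_id\tkind\tdirection\n")
            for nid in sorted(nodes):
                attrs = nodes[nid]
                fh.write(f"{nid}\t{attrs.get('kind', '')}\t{attrs.get('direction', '')}\n")
    elif format == "graphml":
        g = nx.Graph()
        for nid in sorted(nodes):
            g.add_node(nid, **nodes[nid])
        for u, v, r in edges:
            g.add_edge(u, v, interaction="coexp", r=float(r))
        nx.write_graphml(g, str(path))
    else:
        raise ValueError(f"unsupported network format {format!r}")


def read_network(path: str | Path, format: str = "sif"):
    path = Path(path)
    if format == "sif":
        edges: list[tuple[str, str, float]] = []
        with open(path) as fh:
            for raw in fh:
                line = raw.rstrip("\n")
                if not line:
                    continue
                u, _interaction, v = line.split("\t")
                edges.append((u, v, float("nan")))
        nodes: dict[str, dict] = {}
        sidecar = path.with_suffix(path.suffix + ".attrs.tsv")
        if sidecar.exists():
            df = pd.read_csv(sidecar, sep="\t", dtype=str).fillna("")
            for _, row in df.iterrows():
                nodes[row["node_id"]] = {"kind": row["kind"], "direction": row["direction"]}
        else:
            for u, v, _ in edges:
                nodes.setdefault(u, {})
                nodes.setdefault(v, {})
        return nodes, edges
    if format == "graphml":
        g = nx.read_graphml(str(path))
        nodes = {n: dict(g.nodes[n]) for n in g.nodes}
        edges = [(u, v, float(d.get("r", float("nan")))) for u, v, d in g.edges(data=True)]
        return nodes, edges
    raise ValueError(f"unsupported network format {format!r}")
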