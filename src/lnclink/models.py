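"""Shared domain types for the lncRNA target-inference pipeline.

All genomic coordinates are 0-based, half-open ``[start, end)``.  GTF input
(1-based, closed) is converted on read and back on write, so a single
convention governs every distance computation, in particular the 10-kb
cis-proximity rule.

Sequences are stored over the DNA alphabet; RNA input (``U``) is normalized
to ``T`` once, on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

BIOTYPES = ("lncRNA", "mRNA")
CONDITIONS = ("control", "case")

_IUPAC = set("ACGTRYSWKMBDHVN")


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


@dataclass
class GeneModel:
    """One annotated gene/transcript.

    ``exon_length_bp`` is the summed exon length used for RPKM (reads per
    kilobase of transcript per million mapped reads); it may be smaller than
    the genomic span when the gene has introns.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str
    exon_length_bp: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValidationError("gene_id must be non-empty")
        if self.start < 0:
            raise ValidationError(f"{self.gene_id}: start must be >= 0")
        if self.end <= self.start:
            raise ValidationError(
                f"{self.gene_id}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.biotype not in BIOTYPES:
            raise ValidationError(
                f"{self.gene_id}: unknown biotype {self.biotype!r} (expected one of {BIOTYPES})"
            )
        if self.exon_length_bp <= 0:
            raise ValidationError(f"{self.gene_id}: exon_length_bp must be positive")
        if self.exon_length_bp > self.end - self.start:
            raise ValidationError(
                f"{self.gene_id}: exon_length_bp exceeds genomic span"
            )
        if self.sequence is not None:
            self.sequence = normalize_sequence(self.sequence, context=self.gene_id)
            if len(self.sequence) != self.exon_length_bp:
                raise ValidationError(
                    f"{self.gene_id}: sequence length {len(self.sequence)} != "
                    f"exon_length_bp {self.exon_length_bp}"
                )

    @property
    def span(self) -> int:
        return self.end - self.start


def normalize_sequence(seq: str, context: str = "sequence") -> str:
    """Uppercase, map RNA U to T, and reject non-IUPAC characters."""
    out = seq.upper().replace("U", "T")
    bad = set(out) - _IUPAC
    if bad:
        raise ValidationError(f"{context}: non-IUPAC characters {sorted(bad)}")
    return out


def check_unique_gene_ids(genes: Iterable[GeneModel]) -> None:
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValidationError(f"duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)


@dataclass
class SampleTable:
    """Sample/condition design, with optional mapped-read totals (millions)."""

    sample_ids: list[str]
    conditions: list[str]
    mapped_reads_millions: list[float] | None = None

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(set(self.sample_ids)):
            raise ValidationError("sample_ids must be unique")
        if len(self.conditions) != len(self.sample_ids):
            raise ValidationError("conditions and sample_ids differ in length")
        for c in self.conditions:
            if c not in CONDITIONS:
                raise ValidationError(
                    f"unknown condition {c!r} (expected one of {CONDITIONS})"
                )
        for c in CONDITIONS:
            if c not in self.conditions:
                raise ValidationError(f"at least one {c!r} sample required")
        if self.mapped_reads_millions is not None:
            if len(self.mapped_reads_millions) != len(self.sample_ids):
                raise ValidationError("mapped_reads_millions length mismatch")
            if any(m <= 0 for m in self.mapped_reads_millions):
                raise ValidationError("mapped_reads_millions must be positive")

    def ids_for(self, condition: str) -> list[str]:
        return [s for s, c in zip(self.sample_ids, self.conditions) if c == condition]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"sample_id": self.sample_ids, "condition": self.conditions}
        )
        if self.mapped_reads_millions is not None:
            df["mapped_reads_millions"] = self.mapped_reads_millions
        return df


@dataclass
class CountMatrix:
    """Integer read counts, genes x samples, tied to a :class:`SampleTable`."""

    counts: pd.DataFrame
    samples: SampleTable

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples.sample_ids):
            raise ValidationError("count columns must match sample table ids, in order")
        if self.counts.index.duplicated().any():
            raise ValidationError("duplicate gene ids in count matrix")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.round().astype(np.int64)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValidationError("counts must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)


@dataclass
class GeneSet:
    set_id: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.set_id:
            raise ValidationError("set_id must be non-empty")
        if not self.members:
            raise ValidationError(f"{self.set_id}: gene set has no members")
        object.__setattr__(self, "members", frozenset(self.members))


@dataclass
class GeneSetCollection:
    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.set_id for s in self.sets]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate set_ids in collection")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


class OrthologMap(dict):
    """mouse_gene_id -> human_gene_id; many mouse ids may share a human id."""

    def __init__(self, mapping: Mapping[str, str]):
        for k, v in mapping.items():
            if not k or not v:
                raise ValidationError("empty identifier in ortholog map")
        super().__init__(mapping)


@dataclass
class DEResult:
    """Per-gene differential-expression outcome (case over control)."""

    gene_id: str
    biotype: str
    base_mean_control: float
    base_mean_case: float
    log2fc: float
    p: float
    padj: float = float("nan")
    significant: bool = False
    direction: str = "none"


@dataclass
class CisPair:
    """Predicted cis association: lncRNA and mRNA within the gap threshold."""

    lnc_id: str
    mrna_id: str
    gap_bp: int


@dataclass
class TransHit:
    """Predicted trans association via sequence complementarity.

    ``alignment`` holds ``(lnc_start, lnc_end, mrna_start, mrna_end)`` of the
    best local duplex, 0-based half-open on each molecule's own sequence.
    """

    lnc_id: str
    mrna_id: str
    score: float
    energy_G: float
    evalue: float
    alignment: tuple[int, int, int, int]
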