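"""Domain types: loci, gene models, repeats, and coordinate conventions.

Internally every coordinate is 0-based, half-open (``Span``).  GFF3 is the
only 1-based surface and the conversion happens in :mod:`homeolocus.io`.
Minus-strand sequences (spliced CDS, upstream promoter regions) are always
reported on the coding strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

REPEAT_SUPERFAMILIES = (
    "Gypsy",
    "Copia",
    "CACTA",
    "LINE",
    "Harbinger",
    "Mutator",
    "Mariner",
    "unclassified",
)

GENE_STATUSES = ("intact", "pseudogene", "fragment", "excluded")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class Span:
    """0-based half-open interval."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"span start must be non-negative, got {self.start}")
        if self.start >= self.end:
            raise ValueError(f"span must be non-empty: [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Span") -> bool:
        return self.start < other.end and other.start < self.end

    def contains(self, other: "Span") -> bool:
        return self.start <= other.start and other.end <= self.end


@dataclass
class SequenceRecord:
    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record requires an id")
        if not self.residues:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.residues) - DNA_ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(self.residues) if c in bad)
            raise ValueError(
                f"record {self.id!r}: invalid residue {self.residues[pos]!r} at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class GeneModel:
    id: str
    locus_id: str
    strand: str
    span: Span
    exons: List[Span]
    status: str = "intact"
    notes: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: strand must be '+' or '-'")
        if self.status not in GENE_STATUSES:
            raise ValueError(f"gene {self.id}: unknown status {self.status!r}")
        if not self.exons:
            raise ValueError(f"gene {self.id}: at least one exon required")
        self.exons = sorted(self.exons, key=lambda s: s.start)
        prev_end = None
        for exon in self.exons:
            if not self.span.contains(exon):
                raise ValueError(f"gene {self.id}: exon {exon} outside gene span {self.span}")
            if prev_end is not None and exon.start < prev_end:
                raise ValueError(f"gene {self.id}: overlapping exons")
            prev_end = exon.end

    @property
    def cds_length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass
class RepeatFeature:
    span: Span
    rclass: str
    order: str
    superfamily: str
    complete: bool = False

    def __post_init__(self) -> None:
        if self.superfamily not in REPEAT_SUPERFAMILIES:
            raise ValueError(f"unknown repeat superfamily {self.superfamily!r}")


@dataclass
class LocusAnnotation:
    """A locus sequence with its ordered gene models and repeat features."""

    locus_id: str
    genome_tag: str
    sequence: SequenceRecord
    genes: List[GeneModel] = field(default_factory=list)
    repeats: List[RepeatFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: g.span.start)
        seen = set()
        n = len(self.sequence)
        for gene in self.genes:
            if gene.id in seen:
                raise ValueError(f"duplicate gene id {gene.id!r} in locus {self.locus_id}")
            seen.add(gene.id)
            if gene.span.end > n:
                raise ValueError(f"gene {gene.id} extends past locus end ({gene.span.end} > {n})")
        for rep in self.repeats:
            if rep.span.end > n:
                raise ValueError(f"repeat {rep.span} extends past locus end")

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.id == gene_id:
                return g
        raise KeyError(f"no gene {gene_id!r} in locus {self.locus_id}")

    def gene_index(self, gene_id: str) -> int:
        for i, g in enumerate(self.genes):
            if g.id == gene_id:
                return i
        raise KeyError(gene_id)


def extract_cds(locus: LocusAnnotation, gene: GeneModel, allow_n: bool = False) -> str:
    """Spliced CDS on the coding strand (exons concatenated 5'->3')."""
    if gene.locus_id != locus.locus_id:
        raise ValueError(f"gene {gene.id} does not belong to locus {locus.locus_id}")
    seq = locus.sequence.residues
    cds = "".join(seq[e.start:e.end] for e in gene.exons)
    if not allow_n and "N" in cds:
        raise ValueError(f"gene {gene.id}: CDS contains N (assembly gap)")
    if gene.strand == "-":
        cds = reverse_complement(cds)
    return cds


@dataclass
class UpstreamRegion:
    sequence: str
    short: bool  # clipped at the locus boundary


def upstream_region(locus: LocusAnnotation, gene: GeneModel, length: Optional[int] = None) -> UpstreamRegion:
    """The ``length`` bases 5' of the start codon, on the coding strand.

    Clipped at the locus boundary; the ``short`` flag records clipping.
    """
    if gene.locus_id != locus.locus_id:
        raise ValueError(f"gene {gene.id} does not belong to locus {locus.locus_id}")
    if length is None:
        length = 1000
    seq = locus.sequence.residues
    if gene.strand == "+":
        start = max(0, gene.span.start - length)
        region = seq[start:gene.span.start]
        short = gene.span.start - length < 0
    else:
        end = min(len(seq), gene.span.end + length)
        region = reverse_complement(seq[gene.span.end:end])
        short = gene.span.end + length > len(seq)
    return UpstreamRegion(sequence=region, short=short)
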