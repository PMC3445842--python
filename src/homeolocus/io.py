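"""FASTA / GFF3 / TSV readers and writers.

GFF3 files use 1-based closed coordinates; on import they are converted to
the internal 0-based half-open :class:`~homeolocus.model.Span` and genes are
sorted by start.  Each locus is represented by a ``region`` landmark feature
carrying the ``genome_tag`` attribute, ``gene``/``exon`` features and
``repeat_region`` features with ``superfamily``/``repeat_class``/``repeat_order``
attributes.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO

from .model import (
    GeneModel,
    LocusAnnotation,
    RepeatFeature,
    SequenceRecord,
    Span,
)


class ParseError(ValueError):
    pass


def read_fasta(path: str | Path) -> List[SequenceRecord]:
    """Read a (multi-record) FASTA file into validated sequence records."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: List[SequenceRecord] = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        residues = str(rec.seq).upper()
        if not rec.id:
            raise ParseError(f"{path}: record {i} has an empty header")
        try:
            records.append(SequenceRecord(id=rec.id, residues=residues, description=rec.description))
        except ValueError as exc:
            raise ParseError(f"{path}: record {i}: {exc}") from exc
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


def _attr(feature: gffutils.Feature, key: str, default: str | None = None) -> str | None:
    vals = feature.attributes.get(key)
    return vals[0] if vals else default


def read_gff3(path: str | Path, sequences: Sequence[SequenceRecord]) -> List[LocusAnnotation]:
    """Parse gene/exon and repeat features into locus annotations.

    ``sequences`` supplies the locus sequences; every seqid in the file must
    resolve to one of them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    seq_by_id = {rec.id: rec for rec in sequences}
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )

    genome_tags: Dict[str, str] = {}
    for region in db.features_of_type("region"):
        tag = _attr(region, "genome_tag")
        if tag:
            genome_tags[region.seqid] = tag

    genes_by_locus: Dict[str, List[GeneModel]] = {}
    repeats_by_locus: Dict[str, List[RepeatFeature]] = {}
    seen_loci: List[str] = []

    def _locus(seqid: str) -> str:
        if seqid not in seq_by_id:
            raise ParseError(f"{path}: unknown seqid {seqid!r}")
        if seqid not in seen_loci:
            seen_loci.append(seqid)
        return seqid

    for feat in db.features_of_type("gene"):
        seqid = _locus(feat.seqid)
        gene_id = _attr(feat, "ID") or f"gene:{feat.start}"
        span = Span(feat.start - 1, feat.end)
        exons = []
        for child in db.children(feat, featuretype="exon"):
            exon_span = Span(child.start - 1, child.end)
            if not span.contains(exon_span):
                raise ParseError(
                    f"{path}: exon {child.start}..{child.end} outside gene {gene_id} ({feat.start}..{feat.end})"
                )
            exons.append(exon_span)
        if not exons:
            exons = [span]
        notes = feat.attributes.get("note", [])
        gene = GeneModel(
            id=gene_id,
            locus_id=seqid,
            strand=feat.strand if feat.strand in ("+", "-") else "+",
            span=span,
            exons=exons,
            status=_attr(feat, "status", "intact"),
            notes=list(notes),
        )
        genes_by_locus.setdefault(seqid, []).append(gene)

    for feat in db.features_of_type("repeat_region"):
        seqid = _locus(feat.seqid)
        repeats_by_locus.setdefault(seqid, []).append(
            RepeatFeature(
                span=Span(feat.start - 1, feat.end),
                rclass=_attr(feat, "repeat_class", "unclassified"),
                order=_attr(feat, "repeat_order", "unclassified"),
                superfamily=_attr(feat, "superfamily", "unclassified"),
                complete=_attr(feat, "complete", "false").lower() == "true",
            )
        )

    loci = []
    for seqid in seen_loci:
        loci.append(
            LocusAnnotation(
                locus_id=seqid,
                genome_tag=genome_tags.get(seqid, seqid),
                sequence=seq_by_id[seqid],
                genes=genes_by_locus.get(seqid, []),
                repeats=repeats_by_locus.get(seqid, []),
            )
        )
    return loci


def _gff3_line(seqid: str, ftype: str, span: Span, strand: str, attrs: Dict[str, str]) -> str:
    attr_str = ";".join(f"{k}={v}" for k, v in attrs.items())
    return "\t".join(
        [seqid, "homeolocus", ftype, str(span.start + 1), str(span.end), ".", strand, ".", attr_str]
    )


def write_gff3(loci: Iterable[LocusAnnotation], path: str | Path) -> None:
    """Emit 1-based closed GFF3 that re-imports to identical spans."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for locus in loci:
            n = len(locus.sequence)
            fh.write(f"##sequence-region {locus.locus_id} 1 {n}\n")
            fh.write(
                _gff3_line(
                    locus.locus_id,
                    "region",
                    Span(0, n),
                    "+",
                    {"ID": f"region:{locus.locus_id}", "genome_tag": locus.genome_tag},
                )
                + "\n"
            )
            for gene in locus.genes:
                attrs = {"ID": gene.id, "status": gene.status}
                if gene.notes:
                    attrs["note"] = ",".join(gene.notes)
                fh.write(_gff3_line(locus.locus_id, "gene", gene.span, gene.strand, attrs) + "\n")
                for i, exon in enumerate(gene.exons, start=1):
                    fh.write(
                        _gff3_line(
                            locus.locus_id,
                            "exon",
                            exon,
                            gene.strand,
                            {"ID": f"{gene.id}.exon{i}", "Parent": gene.id},
                        )
                        + "\n"
                    )
            for j, rep in enumerate(locus.repeats, start=1):
                fh.write(
                    _gff3_line(
                        locus.locus_id,
                        "repeat_region",
                        rep.span,
                        "+",
                        {
                            "ID": f"{locus.locus_id}.rep{j}",
                            "repeat_class": rep.rclass,
                            "repeat_order": rep.order,
                            "superfamily": rep.superfamily,
                            "complete": str(rep.complete).lower(),
                        },
                    )
                    + "\n"
                )


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
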