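"""Domain types, FASTA/GFF3 I/O and coordinate conventions."""

import pytest

from homeolocus.io import ParseError, read_fasta, read_gff3, write_fasta, write_gff3
from homeolocus.model import (
    GeneModel,
    LocusAnnotation,
    RepeatFeature,
    SequenceRecord,
    Span,
    extract_cds,
    reverse_complement,
    upstream_region,
)


class TestSpan:
    def test_half_open_length(self):
        assert len(Span(9, 20)) == 11

    @pytest.mark.parametrize("start,end", [(-1, 5), (5, 5), (7, 3)])
    def test_invalid_spans_rejected(self, start, end):
        with pytest.raises(ValueError):
            Span(start, end)


class TestFasta:
    def test_minimal_record(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">g1\nACGT\n")
        recs = read_fasta(p)
        assert len(recs) == 1
        assert recs[0].id == "g1" and recs[0].residues == "ACGT"

    def test_multi_record_lengths(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nAC\nGT\n>b\nTT\n")
        recs = read_fasta(p)
        assert [len(r) for r in recs] == [4, 2]

    def test_alphabet_violation_names_position(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">x\nACQT\n")
        with pytest.raises(ParseError, match="Q"):
            read_fasta(p)

    def test_lowercase_uppercased(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">x\nacgtn\n")
        assert read_fasta(p)[0].residues == "ACGTN"

    def test_round_trip(self, tmp_path, rng):
        seq = "".join(rng.choice(list("ACGT"), 211))
        recs = [SequenceRecord(id="r1", residues=seq), SequenceRecord(id="r2", residues="ACGT")]
        path = tmp_path / "rt.fasta"
        write_fasta(recs, path)
        back = read_fasta(path)
        assert [(r.id, r.residues) for r in back] == [(r.id, r.residues) for r in recs]


def _toy_locus():
    seq = SequenceRecord(id="L1", residues="ACGTACGTAC" * 30)
    genes = [
        GeneModel(id="g2", locus_id="L1", strand="+", span=Span(100, 160),
                  exons=[Span(100, 130), Span(140, 160)]),
        GeneModel(id="g1", locus_id="L1", strand="-", span=Span(10, 40), exons=[Span(10, 40)]),
    ]
    repeats = [RepeatFeature(span=Span(200, 260), rclass="Retrotransposon",
                             order="LTR_retrotransposon", superfamily="Gypsy", complete=True)]
    return LocusAnnotation(locus_id="L1", genome_tag="3DS", sequence=seq, genes=genes, repeats=repeats)


class TestGff3:
    def test_genes_sorted_on_construction(self):
        locus = _toy_locus()
        assert [g.id for g in locus.genes] == ["g1", "g2"]

    def test_coordinate_conversion(self, tmp_path):
        fasta = tmp_path / "l.fasta"
        gff = tmp_path / "l.gff3"
        fasta.write_text(">L1\n" + "A" * 50 + "\n")
        gff.write_text(
            "##gff-version 3\n"
            "L1\t.\tgene\t10\t20\t.\t+\t.\tID=g1\n"
            "L1\t.\texon\t10\t20\t.\t+\t.\tID=g1.e1;Parent=g1\n"
        )
        loci = read_gff3(gff, read_fasta(fasta))
        assert loci[0].genes[0].span == Span(9, 20)

    def test_exon_outside_gene_rejected(self, tmp_path):
        fasta = tmp_path / "l.fasta"
        gff = tmp_path / "l.gff3"
        fasta.write_text(">L1\n" + "A" * 50 + "\n")
        gff.write_text(
            "##gff-version 3\n"
            "L1\t.\tgene\t10\t20\t.\t+\t.\tID=g1\n"
            "L1\t.\texon\t10\t25\t.\t+\t.\tID=g1.e1;Parent=g1\n"
        )
        with pytest.raises(ParseError):
            read_gff3(gff, read_fasta(fasta))

    def test_unknown_seqid_rejected(self, tmp_path):
        fasta = tmp_path / "l.fasta"
        gff = tmp_path / "l.gff3"
        fasta.write_text(">L1\nACGT\n")
        gff.write_text("##gff-version 3\nL2\t.\tgene\t1\t4\t.\t+\t.\tID=g1\n")
        with pytest.raises(ParseError):
            read_gff3(gff, read_fasta(fasta))

    def test_round_trip_identity(self, tmp_path):
        locus = _toy_locus()
        gff = tmp_path / "rt.gff3"
        write_gff3([locus], gff)
        back = read_gff3(gff, [locus.sequence])[0]
        assert back.genome_tag == locus.genome_tag
        assert [(g.id, g.strand, g.span, tuple(g.exons), g.status) for g in back.genes] == [
            (g.id, g.strand, g.span, tuple(g.exons), g.status) for g in locus.genes
        ]
        assert [(r.span, r.superfamily, r.complete) for r in back.repeats] == [
            (r.span, r.superfamily, r.complete) for r in locus.repeats
        ]


class TestExtractCds:
    def test_single_exon_plus(self):
        locus = LocusAnnotation(
            locus_id="L", genome_tag="t",
            sequence=SequenceRecord(id="L", residues="ACGTACGT"),
            genes=[GeneModel(id="g", locus_id="L", strand="+", span=Span(0, 6), exons=[Span(0, 6)])],
        )
        assert extract_cds(locus, locus.genes[0]) == "ACGTAC"

    def test_minus_strand_palindrome(self):
        locus = LocusAnnotation(
            locus_id="L", genome_tag="t",
            sequence=SequenceRecord(id="L", residues="ACGT"),
            genes=[GeneModel(id="g", locus_id="L", strand="-", span=Span(0, 4), exons=[Span(0, 4)])],
        )
        assert extract_cds(locus, locus.genes[0]) == "ACGT"  # reverse complement of ACGT

    def test_spliced_hand_case(self):
        locus = LocusAnnotation(
            locus_id="L", genome_tag="t",
            sequence=SequenceRecord(id="L", residues="ACGTACGT"),
            genes=[GeneModel(id="g", locus_id="L", strand="+", span=Span(0, 8),
                             exons=[Span(0, 3), Span(5, 8)])],
        )
        assert extract_cds(locus, locus.genes[0]) == "ACGCGT"

    def test_n_in_cds_rejected_by_default(self):
        locus = LocusAnnotation(
            locus_id="L", genome_tag="t",
            sequence=SequenceRecord(id="L", residues="ACNT"),
            genes=[GeneModel(id="g", locus_id="L", strand="+", span=Span(0, 4), exons=[Span(0, 4)])],
        )
        with pytest.raises(ValueError):
            extract_cds(locus, locus.genes[0])
        assert extract_cds(locus, locus.genes[0], allow_n=True) == "ACNT"

    def test_length_equals_exon_sum(self, paper_fixture):
        for locus in paper_fixture.loci:
            for gene in locus.genes:
                assert len(extract_cds(locus, gene, allow_n=True)) == gene.cds_length


class TestUpstream:
    def test_plus_strand_window(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 2000))
        locus = LocusAnnotation(
            locus_id="L", genome_tag="t",
            sequence=SequenceRecord(id="L", residues=seq),
            genes=[GeneModel(id="g", locus_id="L", strand="+", span=Span(1500, 1600),
                             exons=[Span(1500, 1600)])],
        )
        region = upstream_region(locus, locus.genes[0], 1000)
        assert region.sequence == seq[500:1500]
        assert not region.short

    def test_minus_strand_clipped(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 1000))
        locus = LocusAnnotation(
            locus_id="L", genome_tag="t",
            sequence=SequenceRecord(id="L", residues=seq),
            genes=[GeneModel(id="g", locus_id="L", strand="-", span=Span(100, 200),
                             exons=[Span(100, 200)])],
        )
        region = upstream_region(locus, locus.genes[0], 1000)
        assert region.sequence == reverse_complement(seq[200:1000])
        assert region.short

    def test_short_region_flag(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 100))
        locus = LocusAnnotation(
            locus_id="L", genome_tag="t",
            sequence=SequenceRecord(id="L", residues=seq),
            genes=[GeneModel(id="g", locus_id="L", strand="+", span=Span(10, 50),
                             exons=[Span(10, 50)])],
        )
        region = upstream_region(locus, locus.genes[0], 1000)
        assert len(region.sequence) == 10
        assert region.short
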