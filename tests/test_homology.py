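"""Local alignment, E-value statistics, best-homolog selection, rescue and
fragment merging."""

import math

import numpy as np
import pytest

from homeolocus.homology import (
    HomologyHit,
    align_local,
    evalue,
    find_best_homolog,
    karlin_altschul,
    merge_fragments,
    rescue_against_locus,
)
from homeolocus.model import (
    GeneModel,
    LocusAnnotation,
    SequenceRecord,
    Span,
    reverse_complement,
)
from homeolocus.params import AnalysisParams


def gotoh_local(a: str, b: str, match: int, mismatch: int, gap_open: int, gap_extend: int) -> float:
    """Reference Smith-Waterman with affine gaps (gap of length L costs
    gap_open + L * gap_extend); independent of the production engine."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (vertical consumes b?)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i][j - 1] + gap_extend, H[i][j - 1] + gap_open + gap_extend)
            F[i][j] = max(F[i - 1][j] + gap_extend, H[i - 1][j] + gap_open + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


class TestKarlinAltschul:
    @pytest.mark.parametrize(
        "match,mismatch,lam,k",
        [(1, -2, 1.33, 0.621), (1, -3, 1.374, 0.711)],  # published ungapped values
    )
    def test_reproduces_published_ungapped_statistics(self, match, mismatch, lam, k):
        got_lam, got_k, _ = karlin_altschul(match, mismatch)
        assert got_lam == pytest.approx(lam, abs=0.005)
        assert got_k == pytest.approx(k, abs=0.005)

    def test_evalue_monotone_decreasing_in_score(self, params):
        es = [evalue(s, 1000, 1000, params) for s in range(20, 200, 10)]
        assert all(a > b for a, b in zip(es, es[1:]))


class TestAlignLocal:
    def test_identical_sequences(self, params, rng):
        seq = "".join(rng.choice(list("ACGT"), 200))
        hits = align_local(SequenceRecord(id="q", residues=seq),
                           SequenceRecord(id="s", residues=seq), params)
        top = hits[0]
        assert top.score == 400.0
        assert top.identity == 100.0
        assert top.aln_len == 200
        assert top.evalue < 1e-50

    def test_matches_brute_force_on_short_pairs(self, params, rng):
        bases = np.array(list("ACGT"))
        for _ in range(200):
            a = "".join(rng.choice(bases, rng.integers(5, 13)))
            b = "".join(rng.choice(bases, rng.integers(5, 13)))
            expected = gotoh_local(a, b, params.match_reward, params.mismatch_penalty,
                                   params.gap_open, params.gap_extend)
            hits = align_local(SequenceRecord(id="a", residues=a),
                               SequenceRecord(id="b", residues=b), params,
                               both_strands=False, prefilter=False)
            got = hits[0].score if hits else 0.0
            assert got == expected, (a, b)

    def test_reverse_complement_needs_strand_search(self, params, rng):
        seq = "".join(rng.choice(list("ACGT"), 150))
        q = SequenceRecord(id="q", residues=seq)
        s = SequenceRecord(id="s", residues=reverse_complement(seq))
        both = align_local(q, s, params, both_strands=True)
        assert both and both[0].strand == "-" and both[0].score == 300.0
        fwd_only = align_local(q, s, params, both_strands=False)
        assert not fwd_only or fwd_only[0].score < 100

    def test_empty_sequence_rejected(self, params):
        empty = SequenceRecord.__new__(SequenceRecord)
        empty.id, empty.residues, empty.description = "s", "", ""
        with pytest.raises(ValueError):
            align_local(SequenceRecord(id="q", residues="ACGT"), empty, params)


class TestFindBestHomolog:
    def test_unrelated_subjects_give_none(self, params, rng):
        q = SequenceRecord(id="q", residues="".join(rng.choice(list("ACGT"), 1000)))
        subs = [SequenceRecord(id=f"s{i}", residues="".join(rng.choice(list("ACGT"), 1000)))
                for i in range(5)]
        assert find_best_homolog(q, subs, params) is None

    def test_tie_breaks_to_smaller_id(self, params, rng):
        seq = "".join(rng.choice(list("ACGT"), 300))
        q = SequenceRecord(id="q", residues=seq)
        subs = [SequenceRecord(id="zz", residues=seq), SequenceRecord(id="aa", residues=seq)]
        assert find_best_homolog(q, subs, params).subject_id == "aa"

    def test_empty_subject_set_rejected(self, params):
        with pytest.raises(ValueError):
            find_best_homolog(SequenceRecord(id="q", residues="ACGT"), [], params)

    def test_reciprocal_on_fixture_pairs(self, paper_result, paper_fixture):
        got = {(a, b) for a, b, _ in paper_result.wheat_pairs}
        expected = {
            (r.gene_3DS, r.gene_3B) for r in paper_fixture.pairs_truth.itertuples()
        }
        assert got == expected


def _locus_with_fragment(rng, fragment: str):
    spacer = "".join(rng.choice(list("ACGT"), 2000))
    gene_seq = "".join(rng.choice(list("ACGT"), 600))
    residues = spacer + gene_seq + "".join(rng.choice(list("ACGT"), 500)) + fragment \
        + "".join(rng.choice(list("ACGT"), 400))
    gene = GeneModel(id="annot", locus_id="L", strand="+",
                     span=Span(2000, 2600), exons=[Span(2000, 2600)])
    return LocusAnnotation(
        locus_id="L", genome_tag="3B",
        sequence=SequenceRecord(id="L", residues=residues), genes=[gene],
    ), gene_seq


class TestRescue:
    def test_planted_fragment_recovered(self, params, rng):
        orphan = "".join(rng.choice(list("ACGT"), 900))
        fragment = orphan[200:700]
        locus, _ = _locus_with_fragment(rng, fragment)
        hits = rescue_against_locus(SequenceRecord(id="o", residues=orphan), locus, params)
        frags = [h for h in hits if h.is_candidate_fragment]
        assert len(frags) == 1
        assert len(frags[0].hit.subject_span) == pytest.approx(500, abs=5)

    def test_no_counterpart_gives_empty(self, params, rng):
        orphan = "".join(rng.choice(list("ACGT"), 900))
        locus, _ = _locus_with_fragment(rng, "".join(rng.choice(list("ACGT"), 500)))
        assert rescue_against_locus(SequenceRecord(id="o", residues=orphan), locus, params) == []

    def test_hit_in_annotated_gene_labelled(self, params, rng):
        locus, gene_seq = _locus_with_fragment(rng, "".join(rng.choice(list("ACGT"), 500)))
        hits = rescue_against_locus(SequenceRecord(id="o", residues=gene_seq), locus, params)
        assert hits and hits[0].annotated_gene == "annot"
        assert not hits[0].is_candidate_fragment


def _hit(q, s, qspan, sspan):
    return HomologyHit(query_id=q, subject_id=s, query_span=qspan, subject_span=sspan,
                       identity=99.0, aln_len=len(qspan), score=2.0 * len(qspan), evalue=1e-30)


class TestMergeFragments:
    def _fragments(self):
        fa = GeneModel(id="fA", locus_id="L", strand="+", span=Span(100, 500), exons=[Span(100, 500)])
        fb = GeneModel(id="fB", locus_id="L", strand="+", span=Span(900, 1350), exons=[Span(900, 1350)])
        return fa, fb

    def test_merge_keeps_five_prime_id_and_unions_exons(self):
        fa, fb = self._fragments()
        merged = merge_fragments(
            fb, fa,
            _hit("fB", "H", Span(0, 450), Span(450, 900)),
            _hit("fA", "H", Span(0, 400), Span(0, 400)),
        )
        assert merged.id == "fA"
        assert merged.span == Span(100, 1350)
        assert merged.exons == [Span(100, 500), Span(900, 1350)]
        assert merged.status == "pseudogene"
        # merged coverage of the homolog exceeds 90%
        assert (400 + 450) / 900 > 0.9

    def test_different_homologs_rejected(self):
        fa, fb = self._fragments()
        with pytest.raises(ValueError, match="different homologs"):
            merge_fragments(fa, fb,
                            _hit("fA", "H1", Span(0, 400), Span(0, 400)),
                            _hit("fB", "H2", Span(0, 450), Span(450, 900)))

    def test_overlapping_homolog_intervals_rejected(self):
        fa, fb = self._fragments()
        with pytest.raises(ValueError, match="overlap"):
            merge_fragments(fa, fb,
                            _hit("fA", "H", Span(0, 400), Span(0, 400)),
                            _hit("fB", "H", Span(0, 450), Span(300, 750)))

    def test_overlapping_fragments_rejected(self):
        fa = GeneModel(id="fA", locus_id="L", strand="+", span=Span(100, 500), exons=[Span(100, 500)])
        fb = GeneModel(id="fB", locus_id="L", strand="+", span=Span(400, 800), exons=[Span(400, 800)])
        with pytest.raises(ValueError):
            merge_fragments(fa, fb,
                            _hit("fA", "H", Span(0, 400), Span(0, 400)),
                            _hit("fB", "H", Span(0, 400), Span(450, 850)))
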