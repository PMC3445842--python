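"""EST matching, shared-EST removal, promoter scan and binomial contrast."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from homeolocus._seqgen import random_dna
from homeolocus.expression import (
    ESTHit,
    binomial_contrast,
    drop_shared_ests,
    match_ests,
    scan_promoter,
)
from homeolocus.model import SequenceRecord, reverse_complement
from homeolocus.params import AnalysisParams


def naive_maximal_matches(est: str, cds: str, min_len: int):
    """All maximal exact common substrings by dynamic programming."""
    n, m = len(est), len(cds)
    L = [[0] * (m + 1) for _ in range(n + 1)]
    out = set()
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if est[i - 1] == cds[j - 1]:
                L[i][j] = L[i - 1][j - 1] + 1
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            length = L[i][j]
            if length < min_len:
                continue
            ended = i == n or j == m or est[i] != cds[j]  # maximal to the right
            if ended:
                out.add((i - length, j - length, length))
    return out


class TestMatchEsts:
    def test_planted_exact_substring_hit(self, params, rng):
        cds = random_dna(rng, 600)
        est = cds[100:250]
        hits = match_ests([SequenceRecord(id="g", residues=cds)],
                          [SequenceRecord(id="e", residues=est)], params)
        assert hits and hits[0].match_len == 150 and hits[0].identity == 100.0

    def test_single_mismatch_rejected(self, params, rng):
        cds = random_dna(rng, 600)
        piece = list(cds[100:250])
        piece[75] = {"A": "C", "C": "A", "G": "T", "T": "G"}[piece[75]]
        hits = match_ests([SequenceRecord(id="g", residues=cds)],
                          [SequenceRecord(id="e", residues="".join(piece))], params)
        assert hits == []  # identity 99.3% < 100%

    def test_eighty_bp_exact_rejected(self, params, rng):
        cds = random_dna(rng, 600)
        hits = match_ests([SequenceRecord(id="g", residues=cds)],
                          [SequenceRecord(id="e", residues=cds[100:180])], params)
        assert hits == []  # below the 100 bp minimum

    def test_reverse_strand_matched(self, params, rng):
        cds = random_dna(rng, 600)
        est = reverse_complement(cds[100:250])
        hits = match_ests([SequenceRecord(id="g", residues=cds)],
                          [SequenceRecord(id="e", residues=est)], params)
        assert hits and hits[0].strand == "-"

    def test_matches_naive_oracle(self, rng):
        params = AnalysisParams(est_min_len=12)
        for _ in range(40):
            cds = random_dna(rng, int(rng.integers(60, 300)))
            if rng.random() < 0.7:  # plant a shared stretch
                start = int(rng.integers(0, len(cds) - 40))
                piece = cds[start:start + int(rng.integers(15, 40))]
                est = random_dna(rng, 20) + piece + random_dna(rng, 20)
            else:
                est = random_dna(rng, int(rng.integers(30, 120)))
            got = {
                (h.est_start, h.cds_start, h.match_len)
                for h in match_ests([SequenceRecord(id="g", residues=cds)],
                                    [SequenceRecord(id="e", residues=est)], params)
                if h.strand == "+"
            }
            expected = naive_maximal_matches(est, cds, 12)
            # the k-mer anchored scan reports maximal runs; compare as sets
            assert got == expected


class TestDropSharedEsts:
    def _hits(self, pairs):
        return [ESTHit(est_id=e, gene_id=g, match_len=150) for e, g in pairs]

    def test_pair_spanning_est_removed_entirely(self):
        hits = self._hits([("e1", "a"), ("e1", "b"), ("e2", "a")])
        kept, removed = drop_shared_ests(hits, [("a", "b")])
        assert removed == ["e1"]
        assert {h.est_id for h in kept} == {"e2"}

    def test_unpaired_double_hit_retained(self):
        hits = self._hits([("e1", "a"), ("e1", "c")])
        kept, removed = drop_shared_ests(hits, [("a", "b")])
        assert removed == [] and len(kept) == 2

    def test_no_pairs_is_identity(self):
        hits = self._hits([("e1", "a"), ("e2", "b")])
        kept, removed = drop_shared_ests(hits, [])
        assert kept == hits and removed == []

    def test_fixture_removes_exactly_four(self, paper_result):
        assert len(paper_result.removed_ests) == 4


class TestPromoterScan:
    def _background(self, n):
        return ("CG" * n)[:n]  # A/T-free: no initiator or TATA motifs

    def test_planted_tata_and_initiator(self, params):
        bg = self._background(300)
        region = list(bg)
        region[248:255] = list("CTACATC")  # initiator, TSS at index 250
        region[220:227] = list("TATAAAA")  # 30 bp upstream of the TSS
        call = scan_promoter("".join(region), params)
        assert call.has_promoter
        assert call.tss_offset == 50
        assert call.tata_offset == 30

    def test_tata_too_close_fails_range(self, params):
        bg = self._background(300)
        region = list(bg)
        region[248:255] = list("CTACATC")
        region[240:247] = list("TATAAAA")  # 10 bp upstream: outside 14-38
        call = scan_promoter("".join(region), params)
        assert call.tss_offset == 50
        assert not call.has_promoter

    def test_motif_free_sequence_negative(self, params):
        call = scan_promoter(self._background(600), params)
        assert not call.has_promoter

    def test_short_region_no_call(self, params):
        call = scan_promoter("ACGT" * 10, params)
        assert call.no_call and not call.has_promoter

    def test_fixture_promoter_fractions(self, paper_result):
        table = paper_result.promoters.set_index(["locus", "group"])
        assert table.loc[("3DS", "collinear"), "pct_promoter"] == 73.3
        assert table.loc[("3DS", "non_collinear"), "pct_promoter"] == 54.2
        assert table.loc[("3B", "non_collinear"), "pct_promoter"] == 54.5


class TestBinomialContrast:
    @pytest.mark.parametrize(
        "a,b,p",
        [
            (0, 8, 2 * 0.5**8),   # 0.0078125
            (3, 3, 1.0),
            (1, 7, 0.0703125),    # exact two-tailed sum
        ],
    )
    def test_closed_forms(self, a, b, p):
        assert binomial_contrast(a, b) == pytest.approx(p, rel=1e-12)

    def test_both_zero_flagged(self):
        assert binomial_contrast(0, 0) is None

    @given(st.integers(0, 30), st.integers(0, 30))
    def test_two_tailed_symmetry(self, a, b):
        if a == 0 and b == 0:
            return
        assert binomial_contrast(a, b) == pytest.approx(binomial_contrast(b, a), rel=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            binomial_contrast(-1, 2)
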