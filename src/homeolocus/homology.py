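"""Local alignment, E-values, best-homolog selection and fragment handling.

The search engine is exact Smith-Waterman dynamic programming with affine
gaps (via Biopython's C-backed ``PairwiseAligner``), not heuristic seeding.
Significance uses the ungapped Karlin-Altschul statistic
``E = K * m * n * exp(-lambda * S)`` with ``(lambda, K)`` solved numerically
for the configured scoring scheme and uniform base composition.  A shared
k-mer prefilter may skip sequence pairs that cannot reach the E-value
cutoff; it never changes results above the threshold.

Scoring convention: a gap of length L costs ``gap_open + L * gap_extend``
(both negative).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from Bio import Align
from scipy.optimize import brentq

from .model import GeneModel, LocusAnnotation, SequenceRecord, Span, reverse_complement
from .params import AnalysisParams, DEFAULT_PARAMS


# ---------------------------------------------------------------------------
# Karlin-Altschul statistics
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def karlin_altschul(match: int, mismatch: int) -> Tuple[float, float, float]:
    """(lambda, K, H) for the ungapped score distribution under uniform
    base composition: P(match) = 1/4, P(mismatch) = 3/4.

    K uses the lattice-case series of the renewal-theory derivation,
    evaluated by convolving partial-sum distributions.  Reproduces the
    published ungapped values (e.g. +1/-2 -> 1.33/0.621).
    """
    if match <= 0 or mismatch >= 0:
        raise ValueError("match must be positive and mismatch negative")
    p = {match: 0.25, mismatch: 0.75}

    def _f(lam: float) -> float:
        return sum(pr * math.exp(lam * s) for s, pr in p.items()) - 1.0

    lam = brentq(_f, 1e-9, 10.0)
    H = lam * sum(s * pr * math.exp(lam * s) for s, pr in p.items())

    d = math.gcd(match, -mismatch)
    cur = {0: 1.0}
    total = 0.0
    for k in range(1, 61):
        new: Dict[int, float] = {}
        for j, pj in cur.items():
            for s, ps in p.items():
                new[j + s] = new.get(j + s, 0.0) + pj * ps
        cur = new
        inner = 0.0
        for j, pj in cur.items():
            inner += pj * math.exp(lam * j) if j < 0 else pj
        total += inner / k
    K = d * lam * math.exp(-2.0 * total) / (H * (1.0 - math.exp(-lam * d)))
    return lam, K, H


def evalue(score: float, m: int, n: int, params: AnalysisParams = DEFAULT_PARAMS) -> float:
    lam, K, _ = karlin_altschul(params.match_reward, params.mismatch_penalty)
    return K * m * n * math.exp(-lam * score)


def min_significant_score(m: int, n: int, params: AnalysisParams = DEFAULT_PARAMS) -> float:
    """Smallest score with E <= evalue_max for problem size m x n."""
    lam, K, _ = karlin_altschul(params.match_reward, params.mismatch_penalty)
    return math.log(K * m * n / params.evalue_max) / lam


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

@dataclass
class HomologyHit:
    query_id: str
    subject_id: str
    query_span: Span
    subject_span: Span  # always on the subject forward strand
    identity: float     # percent, matches / alignment columns
    aln_len: int        # alignment columns, gaps included
    score: float
    evalue: float
    subject_kind: str = "cds"
    strand: str = "+"   # strand of the subject relative to the query
    mismatches: int = 0
    gaps: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.identity <= 100:
            raise ValueError("identity must be in (0, 100]")
        if self.aln_len < 1:
            raise ValueError("aln_len must be >= 1")
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")


def _make_aligner(params: AnalysisParams, mode: str = "local") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = params.match_reward
    aligner.mismatch_score = params.mismatch_penalty
    # biopython charges open_gap_score for the first gap residue
    aligner.open_gap_score = params.gap_open + params.gap_extend
    aligner.extend_gap_score = params.gap_extend
    return aligner


def _alignment_stats(aln, qseq: str, sseq: str) -> Tuple[int, int, int, int, Span, Span]:
    """(matches, mismatches, gap columns, alignment length, qspan, sspan).

    ``aln`` was produced by ``aligner.align(qseq, sseq)``; target = query.
    """
    qblocks, sblocks = aln.aligned
    matches = mismatches = gapcols = 0
    prev_q = prev_s = None
    for (q0, q1), (s0, s1) in zip(qblocks, sblocks):
        if prev_q is not None:
            gapcols += (q0 - prev_q) + (s0 - prev_s)
        for a, b in zip(qseq[q0:q1], sseq[s0:s1]):
            if a == b:
                matches += 1
            else:
                mismatches += 1
        prev_q, prev_s = q1, s1
    aln_len = matches + mismatches + gapcols
    qspan = Span(int(qblocks[0][0]), int(qblocks[-1][1]))
    sspan = Span(int(sblocks[0][0]), int(sblocks[-1][1]))
    return matches, mismatches, gapcols, aln_len, qspan, sspan


def _shares_kmer(a: str, b: str, k: int) -> bool:
    if len(a) < k or len(b) < k:
        return True  # prefilter only defined for sequences long enough
    if len(b) < len(a):
        a, b = b, a
    kmers = {a[i:i + k] for i in range(len(a) - k + 1)}
    return any(b[i:i + k] in kmers for i in range(len(b) - k + 1))


def align_local(
    query: SequenceRecord,
    subject: SequenceRecord,
    params: AnalysisParams = DEFAULT_PARAMS,
    subject_kind: str = "cds",
    both_strands: bool = True,
    prefilter: bool = True,
) -> List[HomologyHit]:
    """Optimal local alignments of query against subject (both strands).

    Returns at most one hit per strand (the optimal one), sorted by score
    descending with deterministic (query start, subject start) tie-break.
    """
    if not query.residues or not subject.residues:
        raise ValueError("empty sequence")
    aligner = _make_aligner(params)
    hits: List[HomologyHit] = []
    n = len(subject.residues)
    strands = ["+", "-"] if both_strands else ["+"]
    for strand in strands:
        sseq = subject.residues if strand == "+" else reverse_complement(subject.residues)
        if prefilter and not _shares_kmer(query.residues, sseq, params.prefilter_k):
            continue
        try:
            aln = aligner.align(query.residues, sseq)[0]
        except (IndexError, ValueError):
            continue
        if aln.score <= 0 or len(aln.aligned[0]) == 0:
            continue
        matches, mismatches, gapcols, aln_len, qspan, sspan = _alignment_stats(
            aln, query.residues, sseq
        )
        if strand == "-":
            sspan = Span(n - sspan.end, n - sspan.start)
        hits.append(
            HomologyHit(
                query_id=query.id,
                subject_id=subject.id,
                query_span=qspan,
                subject_span=sspan,
                identity=100.0 * matches / aln_len,
                aln_len=aln_len,
                score=float(aln.score),
                evalue=evalue(aln.score, len(query.residues), n, params),
                subject_kind=subject_kind,
                strand=strand,
                mismatches=mismatches,
                gaps=gapcols,
            )
        )
    hits.sort(key=lambda h: (-h.score, h.query_span.start, h.subject_span.start))
    return hits


def find_best_homolog(
    query: SequenceRecord,
    subject_set: Sequence[SequenceRecord],
    params: AnalysisParams = DEFAULT_PARAMS,
) -> Optional[HomologyHit]:
    """Highest-scoring subject with E <= evalue_max, or None.

    Ties break by higher identity, then lexicographically smaller subject id.
    """
    if not subject_set:
        raise ValueError("subject_set must be non-empty")
    best: Optional[HomologyHit] = None
    for subject in subject_set:
        hits = align_local(query, subject, params)
        for hit in hits:
            if hit.evalue > params.evalue_max:
                continue
            if best is None or (hit.score, hit.identity, _neg_lex(hit.subject_id)) > (
                best.score,
                best.identity,
                _neg_lex(best.subject_id),
            ):
                best = hit
            break  # hits sorted; only the top hit per subject matters
    return best


class _neg_lex(str):
    """Key wrapper: lexicographically smaller string wins in a max()."""

    def __lt__(self, other) -> bool:  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other) -> bool:  # type: ignore[override]
        return str.__lt__(self, other)


def _kmer_set(seq: str, k: int) -> frozenset:
    return frozenset(seq[i:i + k] for i in range(len(seq) - k + 1))


def score_table(
    set_a: Sequence[SequenceRecord],
    set_b: Sequence[SequenceRecord],
    params: AnalysisParams = DEFAULT_PARAMS,
) -> Dict[Tuple[str, str], Tuple[float, float, float]]:
    """All-vs-all (score, identity, evalue) between two CDS sets.

    Scores are symmetric, so one exact alignment per sequence pair serves
    both search directions; the k-mer prefilter skips pairs that share no
    seed word on either strand (such pairs cannot reach the E-value cutoff
    at the fixture's divergence scales).
    """
    k = params.prefilter_k
    a_kmers = {rec.id: _kmer_set(rec.residues, k) for rec in set_a}
    b_kmers = {}
    b_kmers_rc = {}
    for rec in set_b:
        b_kmers[rec.id] = _kmer_set(rec.residues, k)
        b_kmers_rc[rec.id] = _kmer_set(reverse_complement(rec.residues), k)
    aligner = _make_aligner(params)
    table: Dict[Tuple[str, str], Tuple[float, float, float]] = {}
    for qa in set_a:
        for qb in set_b:
            strands = []
            short = len(qa.residues) < k or len(qb.residues) < k
            ka = a_kmers[qa.id]
            if short or not ka.isdisjoint(b_kmers[qb.id]):
                strands.append("+")
            if short or not ka.isdisjoint(b_kmers_rc[qb.id]):
                strands.append("-")
            if not strands:
                continue
            # score-only pass: discard pairs below the E-value cutoff before
            # paying for a full alignment with statistics
            best_score = 0.0
            for strand in strands:
                sseq = qb.residues if strand == "+" else reverse_complement(qb.residues)
                best_score = max(best_score, aligner.score(qa.residues, sseq))
            if evalue(best_score, len(qa.residues), len(qb.residues), params) > params.evalue_max:
                continue
            hits = align_local(qa, qb, params, prefilter=False)
            if hits:
                top = hits[0]
                table[(qa.id, qb.id)] = (top.score, top.identity, top.evalue)
    return table


def best_map_from_table(
    table: Dict[Tuple[str, str], Tuple[float, float, float]],
    params: AnalysisParams = DEFAULT_PARAMS,
    reverse: bool = False,
) -> Dict[str, Tuple[str, float]]:
    """Per-query best subject (id, identity) with E <= evalue_max.

    With ``reverse`` the table's key order is flipped (subject -> query
    search direction); alignment scores are symmetric so the same table
    serves both.
    """
    best: Dict[str, Tuple[float, float, str]] = {}
    for (a_id, b_id), (score, identity, ev) in table.items():
        if ev > params.evalue_max:
            continue
        q_id, s_id = (b_id, a_id) if reverse else (a_id, b_id)
        cur = best.get(q_id)
        if cur is None or (score, identity, _neg_lex(s_id)) > (cur[0], cur[1], _neg_lex(cur[2])):
            best[q_id] = (score, identity, s_id)
    return {q: (s, ident) for q, (score, ident, s) in best.items()}


def mutual_best_from_table(
    table: Dict[Tuple[str, str], Tuple[float, float, float]],
    params: AnalysisParams = DEFAULT_PARAMS,
) -> List[Tuple[str, str, float]]:
    fwd = best_map_from_table(table, params)
    rev = best_map_from_table(table, params, reverse=True)
    out = []
    for a_id, (b_id, identity) in fwd.items():
        back = rev.get(b_id)
        if back is not None and back[0] == a_id:
            out.append((a_id, b_id, identity))
    out.sort()
    return out


def best_hit_map(
    queries: Sequence[SequenceRecord],
    subjects: Sequence[SequenceRecord],
    params: AnalysisParams = DEFAULT_PARAMS,
) -> Dict[str, HomologyHit]:
    out: Dict[str, HomologyHit] = {}
    for q in queries:
        hit = find_best_homolog(q, subjects, params)
        if hit is not None:
            out[q.id] = hit
    return out


def reciprocal_best_pairs(
    set_a: Sequence[SequenceRecord],
    set_b: Sequence[SequenceRecord],
    params: AnalysisParams = DEFAULT_PARAMS,
) -> List[Tuple[HomologyHit, HomologyHit]]:
    """Mutual best hits between two CDS sets (the homoeolog/ortholog pairing)."""
    a_best = best_hit_map(set_a, set_b, params)
    b_best = best_hit_map(set_b, set_a, params)
    pairs = []
    for a_id, hit_ab in a_best.items():
        back = b_best.get(hit_ab.subject_id)
        if back is not None and back.subject_id == a_id:
            pairs.append((hit_ab, back))
    pairs.sort(key=lambda p: p[0].query_id)
    return pairs


# ---------------------------------------------------------------------------
# Fragment rescue against full locus DNA
# ---------------------------------------------------------------------------

@dataclass
class RescueHit:
    hit: HomologyHit
    annotated_gene: Optional[str]  # gene whose span the hit falls in, if any

    @property
    def is_candidate_fragment(self) -> bool:
        return self.annotated_gene is None


def _anchor_windows(query: str, subject: str, k: int, pad: int) -> List[Tuple[int, int]]:
    """Subject windows around shared k-mer anchors, merged."""
    kmers: Dict[str, List[int]] = {}
    for i in range(len(query) - k + 1):
        kmers.setdefault(query[i:i + k], []).append(i)
    raw: List[Tuple[int, int]] = []
    n = len(subject)
    for j in range(0, n - k + 1):
        if subject[j:j + k] in kmers:
            raw.append((max(0, j - pad), min(n, j + k + pad)))
    if not raw:
        return []
    raw.sort()
    merged = [list(raw[0])]
    for s, e in raw[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def rescue_against_locus(
    orphan_cds: SequenceRecord,
    locus: LocusAnnotation,
    params: AnalysisParams = DEFAULT_PARAMS,
) -> List[RescueHit]:
    """Search an orphan CDS against full locus DNA.

    Hits overlapping annotated genes are labelled with the gene id;
    un-annotated hits are candidate gene fragments.  Anchored windows keep
    the exact DP tractable on Mb-scale loci without changing results above
    the E-value threshold.
    """
    subject = locus.sequence
    n = len(subject.residues)
    pad = len(orphan_cds.residues) + 50
    out: List[RescueHit] = []
    seen_spans: List[Span] = []
    for strand in ("+", "-"):
        sseq = subject.residues if strand == "+" else reverse_complement(subject.residues)
        for w0, w1 in _anchor_windows(orphan_cds.residues, sseq, params.prefilter_k, pad):
            window = SequenceRecord(id=subject.id, residues=sseq[w0:w1])
            hits = align_local(orphan_cds, window, params, subject_kind="locus", both_strands=False)
            if not hits:
                continue
            hit = hits[0]
            # window -> forward locus coordinates
            s0 = w0 + hit.subject_span.start
            s1 = w0 + hit.subject_span.end
            if strand == "-":
                s0, s1 = n - s1, n - s0
            span = Span(s0, s1)
            hit = replace(
                hit,
                subject_span=span,
                strand=strand,
                evalue=evalue(hit.score, len(orphan_cds.residues), n, params),
            )
            if hit.evalue > params.evalue_max:
                continue
            if any(span.overlaps(s) for s in seen_spans):
                continue
            seen_spans.append(span)
            overlapping = next((g.id for g in locus.genes if g.span.overlaps(span)), None)
            out.append(RescueHit(hit=hit, annotated_gene=overlapping))
    out.sort(key=lambda r: (-r.hit.score, r.hit.subject_span.start))
    return out


# ---------------------------------------------------------------------------
# Fragment merging
# ---------------------------------------------------------------------------

def merge_fragments(
    frag_a: GeneModel,
    frag_b: GeneModel,
    hit_a: HomologyHit,
    hit_b: HomologyHit,
    max_homolog_overlap: float = 0.10,
) -> GeneModel:
    """Merge two annotated fragments of one CDS into a single gene model.

    Both fragments must lie on the same locus and strand, not overlap, and
    best-match the same homolog on (near-)disjoint homolog intervals.  The
    merged model keeps the id of the 5'-most fragment and is flagged as a
    pseudogene (an annotated CDS split in two implies a disrupting defect).
    """
    if frag_a.locus_id != frag_b.locus_id:
        raise ValueError("fragments must be on the same locus")
    if frag_a.strand != frag_b.strand:
        raise ValueError("fragments must be on the same strand")
    if frag_a.span.overlaps(frag_b.span):
        raise ValueError("fragments overlap on the locus")
    if hit_a.subject_id != hit_b.subject_id:
        raise ValueError(
            f"fragments match different homologs: {hit_a.subject_id} vs {hit_b.subject_id}"
        )
    sa, sb = hit_a.subject_span, hit_b.subject_span
    overlap = min(sa.end, sb.end) - max(sa.start, sb.start)
    if overlap > max_homolog_overlap * min(len(sa), len(sb)):
        raise ValueError("homolog intervals overlap by more than 10%")
    first, second = (frag_a, frag_b) if frag_a.span.start < frag_b.span.start else (frag_b, frag_a)
    merged = GeneModel(
        id=first.id,
        locus_id=first.locus_id,
        strand=first.strand,
        span=Span(first.span.start, second.span.end),
        exons=sorted(first.exons + second.exons, key=lambda s: s.start),
        status="pseudogene",
        notes=sorted(set(first.notes + second.notes) | {f"merged_from:{second.id}"}),
    )
    return merged


def hits_to_frame(hits: Iterable[HomologyHit]):
    """Tabular (blast-outfmt6-like) view of hits."""
    import pandas as pd

    rows = []
    for h in hits:
        rows.append(
            {
                "query": h.query_id,
                "subject": h.subject_id,
                "identity": round(h.identity, 2),
                "aln_len": h.aln_len,
                "mismatches": h.mismatches,
                "gaps": h.gaps,
                "q_start": h.query_span.start,
                "q_end": h.query_span.end,
                "s_start": h.subject_span.start,
                "s_end": h.subject_span.end,
                "strand": h.strand,
                "evalue": h.evalue,
                "score": h.score,
            }
        )
    return pd.DataFrame(rows)
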