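"""Scaffold curation: end matching against small repetitive contigs,
merge-and-gap-fill, and repeat screening of scaffold ends.

Scaffold-end windows are compared to contigs by exact local alignment;
matches are retained at >= 99% identity over >= 100 bp.  Whenever two
different scaffolds match opposite ends of the same contig, they are merged
with the contig's unmatched interior filling the gap; merging iterates to a
fixed point.  Ends carrying a >= 100 bp, > 95%-identity repeat hit are
flagged risky and excluded from merging by default.  Orientation handling
is forward-strand only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .homology import align_local
from .model import SequenceRecord
from .params import AnalysisParams, DEFAULT_PARAMS


@dataclass
class EndMatch:
    scaffold_id: str
    end: str           # left | right
    contig_id: str
    contig_end: Optional[str]  # left | right | None (interior)
    identity: float
    aln_len: int
    scaffold_span: Tuple[int, int]  # scaffold coordinates of the match
    contig_span: Tuple[int, int]

    def __post_init__(self) -> None:
        if self.end not in ("left", "right"):
            raise ValueError("end must be left or right")


def _end_windows(scaffold: SequenceRecord, window: int) -> List[Tuple[str, int, str]]:
    w = min(window, len(scaffold.residues))
    return [
        ("left", 0, scaffold.residues[:w]),
        ("right", len(scaffold.residues) - w, scaffold.residues[-w:]),
    ]


def find_end_matches(
    scaffolds: Sequence[SequenceRecord],
    contigs: Sequence[SequenceRecord],
    end_window: Optional[int] = None,
    params: AnalysisParams = DEFAULT_PARAMS,
    terminus_slack: int = 10,
) -> List[EndMatch]:
    """Align scaffold end windows against contigs; retain matches above the
    merge thresholds and note which contig terminus each match covers."""
    window = end_window or params.end_window
    out: List[EndMatch] = []
    for scaffold in scaffolds:
        for end, offset, seq in _end_windows(scaffold, window):
            query = SequenceRecord(id=f"{scaffold.id}:{end}", residues=seq)
            for contig in contigs:
                hits = align_local(query, contig, params, both_strands=False)
                if not hits:
                    continue
                hit = hits[0]
                if hit.identity < params.merge_min_identity or hit.aln_len < params.merge_min_len:
                    continue
                c0, c1 = hit.subject_span.start, hit.subject_span.end
                contig_end = None
                if c0 <= terminus_slack:
                    contig_end = "left"
                elif c1 >= len(contig.residues) - terminus_slack:
                    contig_end = "right"
                out.append(
                    EndMatch(
                        scaffold_id=scaffold.id,
                        end=end,
                        contig_id=contig.id,
                        contig_end=contig_end,
                        identity=hit.identity,
                        aln_len=hit.aln_len,
                        scaffold_span=(offset + hit.query_span.start, offset + hit.query_span.end),
                        contig_span=(c0, c1),
                    )
                )
    return out


@dataclass
class MergeLogEntry:
    action: str     # merged | conflict | skipped_risky
    contig_id: str
    detail: str


def merge_scaffolds(
    scaffolds: Sequence[SequenceRecord],
    end_matches: Sequence[EndMatch],
    contigs: Sequence[SequenceRecord],
    risky_ends: Optional[Set[Tuple[str, str]]] = None,
) -> Tuple[List[SequenceRecord], List[MergeLogEntry]]:
    """One round of merges from a set of validated end matches.

    A merge requires a scaffold right end on the contig's left part and a
    different scaffold's left end on the contig's right part.  A contig
    matched by more than two scaffold ends is refused and logged.  Risky
    ends (repeat-screen flagged) block the merge unless supported by a
    second independent match on the same contig.
    """
    risky_ends = risky_ends or set()
    by_id = {s.id: s for s in scaffolds}
    contig_by_id = {c.id: c for c in contigs}
    log: List[MergeLogEntry] = []
    merged_away: Set[str] = set()
    new_records: List[SequenceRecord] = []

    by_contig: Dict[str, List[EndMatch]] = {}
    for m in end_matches:
        by_contig.setdefault(m.contig_id, []).append(m)

    for contig_id, matches in sorted(by_contig.items()):
        ends = {(m.scaffold_id, m.end) for m in matches}
        if len(ends) > 2:
            log.append(MergeLogEntry("conflict", contig_id, f"{len(ends)} scaffold ends match"))
            continue
        if len(ends) < 2:
            continue
        lefts = [m for m in matches if m.contig_end == "left" and m.end == "right"]
        rights = [m for m in matches if m.contig_end == "right" and m.end == "left"]
        if not lefts or not rights:
            log.append(MergeLogEntry("conflict", contig_id, "ends do not bracket the contig"))
            continue
        m_left, m_right = lefts[0], rights[0]
        if m_left.scaffold_id == m_right.scaffold_id:
            log.append(MergeLogEntry("conflict", contig_id, "both ends from one scaffold"))
            continue
        if m_left.scaffold_id in merged_away or m_right.scaffold_id in merged_away:
            continue
        risky = {(m.scaffold_id, m.end) for m in (m_left, m_right)} & risky_ends
        if risky:
            supports = {(m.scaffold_id, m.end) for m in matches}
            if len(supports) <= 2:
                log.append(
                    MergeLogEntry("skipped_risky", contig_id, f"risky end(s): {sorted(risky)}")
                )
                continue
        s1 = by_id[m_left.scaffold_id]
        s2 = by_id[m_right.scaffold_id]
        # S1 up to the end of its contig match, the contig's unmatched
        # interior, then S2 from the start of its match; overlapping bases
        # are taken from the scaffolds (higher consensus depth)
        interior_start = m_left.contig_span[1]
        interior_end = m_right.contig_span[0]
        contig_interior = ""
        if interior_end > interior_start:
            contig_interior = contig_by_id[contig_id].residues[interior_start:interior_end]
        merged_seq = (
            s1.residues[: m_left.scaffold_span[1]]
            + contig_interior
            + s2.residues[m_right.scaffold_span[0]:]
        )
        merged = SequenceRecord(id=f"{s1.id}+{s2.id}", residues=merged_seq)
        merged_away.update({s1.id, s2.id})
        new_records.append(merged)
        log.append(MergeLogEntry("merged", contig_id, f"{s1.id}+{s2.id}"))

    result = [s for s in scaffolds if s.id not in merged_away] + new_records
    return result, log


def curate(
    scaffolds: Sequence[SequenceRecord],
    contigs: Sequence[SequenceRecord],
    params: AnalysisParams = DEFAULT_PARAMS,
    repeat_db: Optional[Sequence[SequenceRecord]] = None,
    end_window: Optional[int] = None,
    max_rounds: int = 20,
) -> Tuple[List[SequenceRecord], List[MergeLogEntry]]:
    """Iterate find-matches + merge until a fixed point."""
    risky = set()
    if repeat_db:
        risky = {
            (f.scaffold_id, f.end) for f in screen_end_repeats(scaffolds, repeat_db, params, end_window)
        }
    current = list(scaffolds)
    full_log: List[MergeLogEntry] = []
    for _ in range(max_rounds):
        matches = find_end_matches(current, contigs, end_window, params)
        merged, log = merge_scaffolds(current, matches, contigs, risky_ends=risky)
        full_log.extend(log)
        if {s.id for s in merged} == {s.id for s in current}:
            break
        current = merged
    current.sort(key=lambda s: s.id)
    return current, full_log


@dataclass
class FlaggedEnd:
    scaffold_id: str
    end: str
    repeat_id: str
    identity: float
    aln_len: int


def screen_end_repeats(
    scaffolds: Sequence[SequenceRecord],
    repeat_db: Sequence[SequenceRecord],
    params: AnalysisParams = DEFAULT_PARAMS,
    end_window: Optional[int] = None,
) -> List[FlaggedEnd]:
    """Flag scaffold ends with a >= repeat_screen_min_len bp hit at more than
    repeat_screen_min_identity percent identity against the repeat database."""
    window = end_window or params.end_window
    flagged: List[FlaggedEnd] = []
    for scaffold in scaffolds:
        for end, _offset, seq in _end_windows(scaffold, window):
            query = SequenceRecord(id=f"{scaffold.id}:{end}", residues=seq)
            for repeat in repeat_db:
                hits = align_local(query, repeat, params)
                if not hits:
                    continue
                hit = hits[0]
                if (
                    hit.aln_len >= params.repeat_screen_min_len
                    and hit.identity > params.repeat_screen_min_identity
                ):
                    flagged.append(
                        FlaggedEnd(
                            scaffold_id=scaffold.id,
                            end=end,
                            repeat_id=repeat.id,
                            identity=hit.identity,
                            aln_len=hit.aln_len,
                        )
                    )
                    break
    return flagged
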