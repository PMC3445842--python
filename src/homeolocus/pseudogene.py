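"""CDS integrity assessment and pseudogenization-mechanism attribution.

A CDS is compared with an intact homolog (start-to-stop open reading
frame).  Defects flagged: premature in-frame stop codons (before the final
5% of the homolog ORF), frameshifts (aligned indels of length not a
multiple of 3) and deletions (aligned homolog coverage below 70%, i.e. a
model missing up to 30% of its complete homolog).  Coverage below 50%
with no other defect makes a gene fragment.

Mechanisms follow a fixed priority: insertion of a repetitive element into
an exon-aligned block, a single 1-2 bp frameshifting indel, an internal
deletion anchored on both sides, terminal truncation, otherwise unknown.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .homology import _make_aligner
from .model import Span
from .params import AnalysisParams, DEFAULT_PARAMS

STOP_CODONS = ("TAA", "TAG", "TGA")

MECHANISMS = (
    "TE_INSERTION",
    "POINT_FRAMESHIFT",
    "INTERNAL_DELETION",
    "TERMINAL_TRUNCATION",
    "UNKNOWN",
)


def orf_is_valid(seq: str) -> bool:
    """Start-to-stop ORF: ATG start, terminal stop, no internal in-frame stop."""
    if len(seq) < 6 or len(seq) % 3:
        return False
    if not seq.startswith("ATG"):
        return False
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    if codons[-1] not in STOP_CODONS:
        return False
    return not any(c in STOP_CODONS for c in codons[:-1])


@dataclass
class Defect:
    kind: str                      # premature_stop | frameshift | deletion
    position: Optional[int] = None  # codon index (stop) or CDS position (frameshift)
    coverage: Optional[float] = None


@dataclass
class PseudogeneCall:
    gene_id: str
    status: str                    # intact | pseudogene | fragment
    defects: List[Defect] = field(default_factory=list)
    mechanism: str = "UNKNOWN"
    homolog_id: Optional[str] = None
    coverage: float = 1.0

    def __post_init__(self) -> None:
        if self.status == "pseudogene" and not self.defects:
            raise ValueError("pseudogene call requires at least one defect")
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must be in [0, 1]")


def _aligned_blocks(
    cds: str,
    homolog: str,
    params: AnalysisParams,
    max_rounds: int = 4,
    min_hsp_score: float = 45.0,
):
    """Monotone chain of aligned blocks between two sequences.

    A single optimal local alignment will not bridge a large internal
    deletion (two high-scoring segments beat one gapped path), so local
    alignment is repeated with the previously aligned query interval masked
    out, and the resulting high-scoring segments are chained in coordinate
    order; only segments consistent with the chain are kept.
    """
    aligner = _make_aligner(params, mode="local")
    masked = cds
    hsps = []  # (score, blocks)
    for _ in range(max_rounds):
        try:
            aln = aligner.align(masked, homolog)[0]
        except (IndexError, ValueError):
            break
        if aln.score < min_hsp_score or len(aln.aligned[0]) == 0:
            break
        qb, sb = aln.aligned
        blocks = [(int(q0), int(q1), int(s0), int(s1)) for (q0, q1), (s0, s1) in zip(qb, sb)]
        hsps.append((float(aln.score), blocks))
        q_lo, q_hi = blocks[0][0], blocks[-1][1]
        masked = masked[:q_lo] + "N" * (q_hi - q_lo) + masked[q_hi:]
    if not hsps:
        return []
    # greedy chain: keep the best-scoring HSP, then add others consistent
    # (increasing in both coordinates) in score order; segments may slightly
    # overrun a breakpoint, so small overlaps are tolerated and trimmed
    tol = 25
    hsps.sort(key=lambda h: -h[0])
    kept = [hsps[0][1]]
    for _score, blocks in hsps[1:]:
        ok = True
        for kb in kept:
            before = blocks[-1][1] <= kb[0][0] + tol and blocks[-1][3] <= kb[0][2] + tol
            after = blocks[0][0] >= kb[-1][1] - tol and blocks[0][2] >= kb[-1][3] - tol
            if not (before or after):
                ok = False
                break
        if ok:
            kept.append(blocks)
    merged = []
    for blocks in kept:
        merged.extend(list(b) for b in blocks)
    merged.sort(key=lambda b: b[0])
    trimmed = []
    for b in merged:
        q0, q1, s0, s1 = b
        if trimmed:
            cut = max(0, trimmed[-1][1] - q0, trimmed[-1][3] - s0)
            q0 += cut
            s0 += cut
        if q0 < q1 and s0 < s1:
            trimmed.append([q0, q1, s0, s1])
    return [tuple(b) for b in trimmed]


def assess_integrity(
    cds: str,
    intact_homolog_cds: str,
    params: AnalysisParams = DEFAULT_PARAMS,
    gene_id: str = "",
    homolog_id: Optional[str] = None,
) -> PseudogeneCall:
    """Classify a CDS as intact, pseudogene or fragment against an intact homolog."""
    if not orf_is_valid(intact_homolog_cds):
        raise ValueError("intact homolog must be a start-to-stop open reading frame")
    defects: List[Defect] = []
    if cds == intact_homolog_cds:
        return PseudogeneCall(gene_id=gene_id, status="intact", homolog_id=homolog_id)

    blocks = _aligned_blocks(cds, intact_homolog_cds, params)
    hlen = len(intact_homolog_cds)
    covered = sum(s1 - s0 for _, _, s0, s1 in blocks)
    coverage = covered / hlen

    # frameshifts: inter-block indels with net length not a multiple of 3.
    # A shifted frame must persist for >= frameshift_min_extent bases before
    # being compensated — nearby +1/-1 gap pairs are alignment noise at high
    # divergence, not disabling mutations.
    frame = 0
    shift_start = None
    for (pq0, pq1, ps0, ps1), (q0, q1, s0, s1) in zip(blocks, blocks[1:]):
        ins = q0 - pq1       # extra CDS bases (insertion)
        dele = s0 - ps1      # skipped homolog bases (deletion)
        frame = (frame + ins - dele) % 3
        if frame != 0 and shift_start is None:
            shift_start = pq1
        elif frame == 0 and shift_start is not None:
            if q0 - shift_start >= params.frameshift_min_extent:
                defects.append(Defect(kind="frameshift", position=shift_start))
            shift_start = None
    if shift_start is not None and blocks[-1][1] - shift_start >= params.frameshift_min_extent:
        defects.append(Defect(kind="frameshift", position=shift_start))

    # premature stops, read in the homolog-anchored frame; blocks entered
    # with a shifted frame are skipped (their codon readout is arbitrary)
    tail = hlen * (1.0 - params.premature_stop_tail_frac)
    entering_frame = [0]
    for (pq0, pq1, ps0, ps1), (q0, q1, s0, s1) in zip(blocks, blocks[1:]):
        entering_frame.append((entering_frame[-1] + (q0 - pq1) - (s0 - ps1)) % 3)
    found_stop = False
    for (q0, q1, s0, s1), frame in zip(blocks, entering_frame):
        if found_stop or frame != 0:
            continue
        lead = (-s0) % 3
        for off in range(lead, (s1 - s0) - 2, 3):
            h = s0 + off
            if h + 3 > hlen - 3:  # the homolog's own terminal stop is not premature
                break
            codon = cds[q0 + off:q0 + off + 3]
            if codon in STOP_CODONS and h < tail:
                defects.append(Defect(kind="premature_stop", position=h // 3))
                found_stop = True
                break

    if coverage < 1.0 - params.pseudo_deletion_frac:
        defects.append(Defect(kind="deletion", coverage=coverage))

    if coverage < params.fragment_coverage and all(d.kind == "deletion" for d in defects):
        status = "fragment"
    elif defects:
        status = "pseudogene"
    else:
        status = "intact"
    return PseudogeneCall(
        gene_id=gene_id,
        status=status,
        defects=defects,
        homolog_id=homolog_id,
        coverage=min(coverage, 1.0),
    )


def attribute_mechanism(
    gene_region: str,
    pseudo_region: str,
    repeats: Sequence[Span],
    exons: Sequence[Span],
    params: AnalysisParams = DEFAULT_PARAMS,
) -> str:
    """Attribute the pseudogenization mechanism for a gene-pseudogene pair.

    ``gene_region``/``pseudo_region`` are the intact and defective sequences
    with flanks; ``repeats`` are repeat spans in pseudo-region coordinates
    and ``exons`` exon spans in gene-region coordinates.  Exactly one
    mechanism is returned, in priority order TE insertion > point
    frameshift > internal deletion > terminal truncation > unknown.
    """
    blocks = _aligned_blocks(pseudo_region, gene_region, params)
    if not blocks:
        return "UNKNOWN"

    def overlaps_exon(g0: int, g1: int) -> bool:
        return any(e.start < g1 and g0 < e.end for e in exons)

    events: List[Tuple[int, int, int]] = []  # (pseudo insertion len, gene deletion len, gene pos)
    for (pq0, pq1, ps0, ps1), (q0, q1, s0, s1) in zip(blocks, blocks[1:]):
        events.append((q0 - pq1, s0 - ps1, ps1))

    # 1) repetitive element inserted into an exon-aligned block;
    #    intron-against-intron gaps have unaligned sequence on both sides,
    #    so a true insertion requires (almost) nothing deleted opposite it
    for (pq0, pq1, ps0, ps1), (q0, q1, s0, s1) in zip(blocks, blocks[1:]):
        ins_len = q0 - pq1
        del_len = s0 - ps1
        if ins_len >= params.min_te_insertion and del_len <= 10:
            inserted = Span(pq1, q0)
            hit_repeat = any(r.start < inserted.end and inserted.start < r.end for r in repeats)
            if hit_repeat and (overlaps_exon(ps1 - 1, ps1 + 1) or overlaps_exon(s0 - 1, s0 + 1)):
                return "TE_INSERTION"

    # 2) a single small (1-2 bp) frameshifting indel
    small = [e for e in events if 1 <= max(e[0], e[1]) <= 2 and (e[0] - e[1]) % 3 != 0]
    if len(small) == 1 and len(events) == len(small):
        return "POINT_FRAMESHIFT"

    # 3) internal deletion, anchored by aligned blocks on both sides
    for ins_len, del_len, _pos in events:
        if del_len >= params.min_internal_deletion and ins_len <= 10:
            return "INTERNAL_DELETION"

    # 4) terminal truncation: a CDS terminus has no homology in the pseudo region
    g0 = blocks[0][2]
    g1 = blocks[-1][3]
    if exons:
        cds_start = min(e.start for e in exons)
        cds_end = max(e.end for e in exons)
    else:
        cds_start, cds_end = 0, len(gene_region)
    missing_5p = max(0, g0 - cds_start)
    missing_3p = max(0, cds_end - g1)
    if max(missing_5p, missing_3p) >= params.min_internal_deletion:
        return "TERMINAL_TRUNCATION"
    return "UNKNOWN"


def pseudogene_census(
    calls: Dict[str, PseudogeneCall],
    profiles: Sequence,
) -> pd.DataFrame:
    """Per-locus pseudogene/fragment totals cross-tabbed against categories.

    The "non-collinear pseudogene" count excludes TANDEM_DUP_NC copies of
    collinear genes (a duplicate of a collinear gene is not an inserted
    non-collinear pseudogene).
    """
    prof_by_id = {p.gene_id: p for p in profiles}
    unknown = set(calls) - set(prof_by_id)
    if unknown:
        raise ValueError(f"calls for genes missing from profiles: {sorted(unknown)[:5]}")
    rows: Dict[str, Dict[str, int]] = {}
    for gid, call in sorted(calls.items()):
        prof = prof_by_id[gid]
        row = rows.setdefault(
            prof.genome_tag,
            {"n_assessed": 0, "n_pseudogene": 0, "n_fragment": 0,
             "n_pseudo_or_fragment": 0, "n_noncollinear_pseudo": 0},
        )
        row["n_assessed"] += 1
        if call.status == "pseudogene":
            row["n_pseudogene"] += 1
        elif call.status == "fragment":
            row["n_fragment"] += 1
        if call.status in ("pseudogene", "fragment"):
            row["n_pseudo_or_fragment"] += 1
            if prof.category in ("SHARED_WHEAT_NC", "LOCUS_SPECIFIC_NC"):
                row["n_noncollinear_pseudo"] += 1
            elif prof.category == "TANDEM_DUP_NC":
                partner = prof.tandem_partner
                partner_prof = prof_by_id.get(partner) if partner else None
                partner_collinear = partner_prof is not None and partner_prof.category in (
                    "COLLINEAR_ALL",
                    "COLLINEAR_RICE_WHEAT",
                )
                if not partner_collinear:
                    row["n_noncollinear_pseudo"] += 1
    out = [{"genome": genome, **vals} for genome, vals in sorted(rows.items())]
    if not out:
        return pd.DataFrame(
            columns=["genome", "n_assessed", "n_pseudogene", "n_fragment",
                     "n_pseudo_or_fragment", "n_noncollinear_pseudo"]
        )
    return pd.DataFrame(out)
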