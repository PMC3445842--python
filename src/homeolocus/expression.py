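"""EST-based expression scoring, shared-EST removal, promoter scanning and
the per-pair binomial expression contrast.

Expression evidence follows the strict rule: only exact matches (100%
identity) of at least 100 bp between an EST and a CDS count; ESTs hitting
both members of a homoeologous pair cannot be assigned to either copy and
are removed entirely.  The promoter scan is a deliberately simple,
documented replacement for a polymerase-II promoter predictor: a
pyrimidine-purine initiator consensus (YYANWYY) near the start codon and a
TATAWAW box 14-38 bp upstream of the chosen TSS.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd
from scipy.stats import binomtest

from .collinearity import (
    COLLINEAR_CATEGORIES,
    NONCOLLINEAR_CATEGORIES,
    round_half_up,
)
from .model import SequenceRecord, reverse_complement
from .params import AnalysisParams, DEFAULT_PARAMS

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "Y": "CT", "R": "AG", "W": "AT", "N": "ACGT",
}

INR_CONSENSUS = "YYANWYY"  # TSS at the A (index 2)
TATA_CONSENSUS = "TATAWAW"


@dataclass
class ESTHit:
    est_id: str
    gene_id: str
    match_len: int
    identity: float = 100.0
    est_start: int = 0
    cds_start: int = 0
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.match_len < 1:
            raise ValueError("match_len must be positive")


_INDEX_K = 20


def _kmer_index(cds: str, k: int = _INDEX_K) -> Dict[str, List[int]]:
    index: Dict[str, List[int]] = {}
    for i in range(len(cds) - k + 1):
        index.setdefault(cds[i:i + k], []).append(i)
    return index


def _maximal_exact_matches(
    est: str,
    cds: str,
    min_len: int,
    index: Optional[Dict[str, List[int]]] = None,
) -> List[Tuple[int, int, int]]:
    """All maximal exact common substrings of length >= min_len as
    (est_start, cds_start, length), found by k-mer anchoring and extension."""
    k = min(_INDEX_K, min_len)
    if len(est) < k or len(cds) < k:
        return []
    if index is None or k != _INDEX_K:
        index = _kmer_index(cds, k)
    seen: Set[Tuple[int, int]] = set()  # (diagonal, est_end) of reported maximal runs
    out = []
    for j in range(len(est) - k + 1):
        for i in index.get(est[j:j + k], ()):
            diag = j - i
            # extend left
            a, b = j, i
            while a > 0 and b > 0 and est[a - 1] == cds[b - 1]:
                a -= 1
                b -= 1
            # extend right
            a2, b2 = j + k, i + k
            while a2 < len(est) and b2 < len(cds) and est[a2] == cds[b2]:
                a2 += 1
                b2 += 1
            key = (diag, a2)
            if key in seen:
                continue
            seen.add(key)
            if a2 - a >= min_len:
                out.append((a, b, a2 - a))
    out.sort()
    return out


def match_ests(
    cds_set: Sequence[SequenceRecord],
    est_set: Sequence[SequenceRecord],
    params: AnalysisParams = DEFAULT_PARAMS,
) -> List[ESTHit]:
    """Exact EST-to-CDS matches (both strands) of >= est_min_len bases.

    With the default 100% identity requirement this is pure exact substring
    matching; no mismatches are tolerated.
    """
    if params.est_min_identity < 100.0:
        raise NotImplementedError("only the exact-match rule (100% identity) is implemented")
    hits: List[ESTHit] = []
    indexes = {cds.id: _kmer_index(cds.residues) for cds in cds_set} \
        if params.est_min_len >= _INDEX_K else {}
    for est in est_set:
        for strand in ("+", "-"):
            eseq = est.residues if strand == "+" else reverse_complement(est.residues)
            for cds in cds_set:
                for e0, c0, length in _maximal_exact_matches(
                    eseq, cds.residues, params.est_min_len, indexes.get(cds.id)
                ):
                    hits.append(
                        ESTHit(
                            est_id=est.id,
                            gene_id=cds.id,
                            match_len=length,
                            identity=100.0,
                            est_start=e0,
                            cds_start=c0,
                            strand=strand,
                        )
                    )
    return hits


def drop_shared_ests(
    hits: Sequence[ESTHit],
    homoeolog_pairs: Sequence[Tuple[str, str]],
) -> Tuple[List[ESTHit], List[str]]:
    """Remove every hit of any EST that matches both members of a pair."""
    pair_sets = [frozenset(p) for p in homoeolog_pairs]
    genes_by_est: Dict[str, Set[str]] = {}
    for h in hits:
        genes_by_est.setdefault(h.est_id, set()).add(h.gene_id)
    removed = sorted(
        est_id
        for est_id, genes in genes_by_est.items()
        if any(pair <= genes for pair in pair_sets)
    )
    removed_set = set(removed)
    return [h for h in hits if h.est_id not in removed_set], removed


def expression_summary(
    hits: Sequence[ESTHit],
    profiles: Sequence,
    wheat_tags: Tuple[str, str] = ("3DS", "3B"),
) -> pd.DataFrame:
    """Expressed-gene fractions per locus for collinear vs non-collinear genes.

    A gene is expressed iff it has at least one retained hit.  Non-collinear
    pools SHARED_WHEAT_NC, LOCUS_SPECIFIC_NC and TANDEM_DUP_NC; EXCLUDED
    genes are left out.
    """
    expressed = {h.gene_id for h in hits}
    rows = []
    for tag in wheat_tags:
        for group, cats in (("collinear", COLLINEAR_CATEGORIES), ("non_collinear", NONCOLLINEAR_CATEGORIES)):
            genes = [p for p in profiles if p.genome_tag == tag and p.category in cats]
            n = len(genes)
            n_expr = sum(1 for p in genes if p.gene_id in expressed)
            rows.append(
                {
                    "locus": tag,
                    "group": group,
                    "n_genes": n,
                    "n_expressed": n_expr,
                    "pct_expressed": round_half_up(100.0 * n_expr / n, 1) if n else 0.0,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Promoter scan
# ---------------------------------------------------------------------------

@dataclass
class PromoterCall:
    gene_id: str
    tss_offset: Optional[int]   # bp upstream of the start codon
    tata_offset: Optional[int]  # bp upstream of the TSS, within tata_tss_range
    has_promoter: bool
    tss_score: int = 0
    no_call: bool = False       # region too short to scan


def _motif_score(window: str, consensus: str) -> int:
    return sum(1 for base, sym in zip(window, consensus) if base in _IUPAC[sym])


def scan_promoter(
    upstream: str,
    params: AnalysisParams = DEFAULT_PARAMS,
    gene_id: str = "",
) -> PromoterCall:
    """TSS/TATA scan of an upstream region given on the coding strand.

    The TSS is the highest-scoring initiator-consensus position within the
    final ``tss_search_window`` bases (closest to the start codon wins
    ties); the TATA box is a perfect TATAWAW whose distance to the TSS
    falls in ``tata_tss_range``.
    """
    n = len(upstream)
    if n < 50:
        return PromoterCall(gene_id=gene_id, tss_offset=None, tata_offset=None,
                            has_promoter=False, no_call=True)
    inr_len = len(INR_CONSENSUS)
    window_start = max(0, n - params.tss_search_window)
    best_score = -1
    best_pos = None  # index of the initiator A
    for i in range(window_start, n - inr_len + 1):
        score = _motif_score(upstream[i:i + inr_len], INR_CONSENSUS)
        if score >= best_score:  # >= prefers the position closest to the ATG
            best_score = score
            best_pos = i + 2
    if best_pos is None or best_score < params.min_inr_score:
        return PromoterCall(gene_id=gene_id, tss_offset=None, tata_offset=None, has_promoter=False)
    tss_offset = n - best_pos

    tata_offset = None
    lo, hi = params.tata_tss_range
    tlen = len(TATA_CONSENSUS)
    for dist in range(lo, hi + 1):  # prefer the most proximal perfect box
        start = best_pos - dist
        if start < 0 or start + tlen > n:
            continue
        if _motif_score(upstream[start:start + tlen], TATA_CONSENSUS) == tlen:
            tata_offset = dist
            break
    tata_less = (
        params.tata_less_min_score is not None and best_score >= params.tata_less_min_score
    )
    has_promoter = tata_offset is not None or tata_less
    return PromoterCall(
        gene_id=gene_id,
        tss_offset=tss_offset,
        tata_offset=tata_offset,
        has_promoter=has_promoter,
        tss_score=best_score,
    )


def promoter_summary(
    calls: Sequence[PromoterCall],
    profiles: Sequence,
    wheat_tags: Tuple[str, str] = ("3DS", "3B"),
) -> pd.DataFrame:
    by_id = {c.gene_id: c for c in calls}
    rows = []
    for tag in wheat_tags:
        for group, cats in (("collinear", COLLINEAR_CATEGORIES), ("non_collinear", NONCOLLINEAR_CATEGORIES)):
            genes = [p for p in profiles if p.genome_tag == tag and p.category in cats]
            n = len(genes)
            n_prom = sum(1 for p in genes if by_id.get(p.gene_id) and by_id[p.gene_id].has_promoter)
            rows.append(
                {
                    "locus": tag,
                    "group": group,
                    "n_genes": n,
                    "n_promoter": n_prom,
                    "pct_promoter": round_half_up(100.0 * n_prom / n, 1) if n else 0.0,
                }
            )
    return pd.DataFrame(rows)


def binomial_contrast(hits_a: int, hits_b: int) -> Optional[float]:
    """Exact two-tailed binomial p-value for H0: p = 0.5 on hits_a successes
    out of hits_a + hits_b trials.  Returns None when both counts are zero."""
    if hits_a < 0 or hits_b < 0:
        raise ValueError("counts must be non-negative")
    n = hits_a + hits_b
    if n == 0:
        return None
    return float(binomtest(hits_a, n, 0.5, alternative="two-sided").pvalue)
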