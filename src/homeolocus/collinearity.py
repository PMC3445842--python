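"""Four-genome gene correspondence: anchor chaining, tandem resolution,
collinearity classification and summary statistics.

"Collinear position" is operationalized as membership in the maximum-weight
order-preserving anchor chain between two loci (longest-increasing-
subsequence dynamic programming over best-homolog pairs).  Chains are
computed on gene order irrespective of strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .model import LocusAnnotation, RepeatFeature

CATEGORIES = (
    "COLLINEAR_ALL",
    "COLLINEAR_RICE_WHEAT",
    "SHARED_WHEAT_NC",
    "LOCUS_SPECIFIC_NC",
    "TANDEM_DUP_NC",
    "EXCLUDED",
)

COLLINEAR_CATEGORIES = ("COLLINEAR_ALL", "COLLINEAR_RICE_WHEAT")
NONCOLLINEAR_CATEGORIES = ("SHARED_WHEAT_NC", "LOCUS_SPECIFIC_NC", "TANDEM_DUP_NC")


def round_half_up(value: float, ndigits: int = 1) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Anchor chaining
# ---------------------------------------------------------------------------

@dataclass
class AnchorChain:
    """Order-preserving chain of (gene_a_index, gene_b_index) anchors."""

    anchors: List[Tuple[int, int]]
    weight: float

    def __post_init__(self) -> None:
        for (a0, b0), (a1, b1) in zip(self.anchors, self.anchors[1:]):
            if not (a0 < a1 and b0 < b1):
                raise ValueError("chain must be strictly increasing in both coordinates")

    def __len__(self) -> int:
        return len(self.anchors)

    def __contains__(self, anchor: Tuple[int, int]) -> bool:
        return anchor in set(self.anchors)


def chain_anchors(pairs: Sequence[Tuple[int, int, float]]) -> AnchorChain:
    """Maximum-weight strictly increasing chain over best-homolog pairs.

    ``pairs`` is a list of (index_a, index_b, weight); each gene index may
    appear at most once.  Ties break toward the chain containing the
    earlier query gene (lexicographically smallest index sequence).
    """
    seen_a = set()
    seen_b = set()
    for a, b, _ in pairs:
        if a in seen_a or b in seen_b:
            raise ValueError("each gene may appear in at most one anchor pair")
        seen_a.add(a)
        seen_b.add(b)
    if not pairs:
        return AnchorChain(anchors=[], weight=0.0)
    order = sorted(range(len(pairs)), key=lambda i: (pairs[i][0], pairs[i][1]))
    best_w = [0.0] * len(pairs)
    prev: List[Optional[int]] = [None] * len(pairs)
    for oi, i in enumerate(order):
        ai, bi, wi = pairs[i]
        best_w[i] = wi
        for j in (order[oj] for oj in range(oi)):
            aj, bj, wj = pairs[j]
            if aj < ai and bj < bi and best_w[j] + wi > best_w[i]:
                best_w[i] = best_w[j] + wi
                prev[i] = j
    # pick the endpoint with the maximal weight; on ties prefer the chain
    # whose anchor index sequence is lexicographically smallest
    def _chain_from(i: int) -> List[int]:
        out = []
        cur: Optional[int] = i
        while cur is not None:
            out.append(cur)
            cur = prev[cur]
        return out[::-1]

    best_i = None
    best_key = None
    for i in range(len(pairs)):
        key = (-best_w[i], [pairs[j][0] for j in _chain_from(i)])
        if best_key is None or key < best_key:
            best_key = key
            best_i = i
    chain_idx = _chain_from(best_i)  # type: ignore[arg-type]
    anchors = [(pairs[j][0], pairs[j][1]) for j in chain_idx]
    return AnchorChain(anchors=anchors, weight=best_w[best_i])  # type: ignore[index]


# ---------------------------------------------------------------------------
# Profiles and classification
# ---------------------------------------------------------------------------

@dataclass
class CollinearityProfile:
    gene_id: str
    genome_tag: str
    homologs: Dict[str, Tuple[Optional[str], float]] = field(default_factory=dict)
    in_chain: Dict[str, bool] = field(default_factory=dict)
    category: str = "LOCUS_SPECIFIC_NC"
    tandem_partner: Optional[str] = None
    status: str = "intact"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def classify_genes(
    loci: Dict[str, LocusAnnotation],
    pair_maps: Dict[Tuple[str, str], Dict[str, Tuple[str, float]]],
    chains: Dict[Tuple[str, str], set],
    wheat_tags: Tuple[str, str] = ("3DS", "3B"),
    brachy_tag: str = "Bd2",
    rice_tag: str = "Os1",
) -> List[CollinearityProfile]:
    """Assign exactly one category to every gene of every genome.

    ``pair_maps[(tag_a, tag_b)]`` maps gene ids of ``tag_a`` to their
    reciprocal-best partner (id, identity) in ``tag_b`` (both directions
    present).  ``chains[(tag_a, tag_b)]`` is the set of (gene_id_a,
    gene_id_b) anchors in the maximum-weight chain.
    """
    d_tag, b_tag = wheat_tags
    profiles: List[CollinearityProfile] = []

    def pair(tag_a: str, tag_b: str, gid: str) -> Optional[Tuple[str, float]]:
        return pair_maps.get((tag_a, tag_b), {}).get(gid)

    def in_chain(tag_a: str, tag_b: str, gid_a: str, gid_b: str) -> bool:
        key = (tag_a, tag_b) if (tag_a, tag_b) in chains else (tag_b, tag_a)
        anchors = chains.get(key, set())
        return (gid_a, gid_b) in anchors or (gid_b, gid_a) in anchors

    for wtag, other_wtag in ((d_tag, b_tag), (b_tag, d_tag)):
        locus = loci[wtag]
        for gene in locus.genes:
            prof = CollinearityProfile(gene_id=gene.id, genome_tag=wtag, status=gene.status)
            if gene.status == "excluded":
                prof.category = "EXCLUDED"
                profiles.append(prof)
                continue
            wpair = pair(wtag, other_wtag, gene.id)
            bd = pair(wtag, brachy_tag, gene.id)
            os_ = pair(wtag, rice_tag, gene.id)
            prof.homologs[other_wtag] = (wpair[0], wpair[1]) if wpair else (None, 0.0)
            prof.homologs[brachy_tag] = (bd[0], bd[1]) if bd else (None, 0.0)
            prof.homologs[rice_tag] = (os_[0], os_[1]) if os_ else (None, 0.0)
            prof.in_chain[other_wtag] = bool(wpair) and in_chain(wtag, other_wtag, gene.id, wpair[0])
            prof.in_chain[brachy_tag] = bool(bd) and in_chain(wtag, brachy_tag, gene.id, bd[0])
            prof.in_chain[rice_tag] = bool(os_) and in_chain(wtag, rice_tag, gene.id, os_[0])
            if wpair is None:
                prof.category = "LOCUS_SPECIFIC_NC"
            elif prof.in_chain[brachy_tag] and prof.in_chain[rice_tag]:
                prof.category = "COLLINEAR_ALL"
            elif prof.in_chain[rice_tag] and bd is None:
                prof.category = "COLLINEAR_RICE_WHEAT"
            else:
                prof.category = "SHARED_WHEAT_NC"
            profiles.append(prof)

    for mtag in (brachy_tag, rice_tag):
        if mtag not in loci:
            continue
        for gene in loci[mtag].genes:
            prof = CollinearityProfile(gene_id=gene.id, genome_tag=mtag, status=gene.status)
            chain_d = chain_b = False
            for wtag, flag_name in ((d_tag, "d"), (b_tag, "b")):
                p = pair(mtag, wtag, gene.id)
                prof.homologs[wtag] = (p[0], p[1]) if p else (None, 0.0)
                hit_chain = bool(p) and in_chain(mtag, wtag, gene.id, p[0])
                prof.in_chain[wtag] = hit_chain
                if wtag == d_tag:
                    chain_d = hit_chain
                else:
                    chain_b = hit_chain
            if chain_d and chain_b:
                other_model = rice_tag if mtag == brachy_tag else brachy_tag
                # conserved in both wheat loci; four-way if the other model
                # genome also carries the family at a collinear position
                partner_d = prof.homologs[d_tag][0]
                four_way = False
                if partner_d is not None:
                    p = pair(d_tag, other_model, partner_d)
                    four_way = bool(p) and in_chain(d_tag, other_model, partner_d, p[0])
                prof.category = "COLLINEAR_ALL" if four_way else "COLLINEAR_RICE_WHEAT"
            else:
                prof.category = "LOCUS_SPECIFIC_NC"
            profiles.append(prof)
    return profiles


def resolve_tandem(
    locus: LocusAnnotation,
    profiles: List[CollinearityProfile],
    ortholog_best: Dict[str, Dict[str, Tuple[str, float]]],
    max_intervening: int = 1,
) -> List[CollinearityProfile]:
    """Resolve tandem duplications within one locus.

    A tandem array is a run of nearby genes (at most ``max_intervening``
    genes apart) whose best cross-species homolog is the same model-genome
    gene.  The copy with the highest identity to that homolog keeps its
    collinear eligibility; the remaining copies become TANDEM_DUP_NC with
    the kept copy recorded as tandem partner.  Identity ties go to the
    5'-most copy.
    """
    prof_by_id = {p.gene_id: p for p in profiles if p.genome_tag == locus.genome_tag}
    order = [g.id for g in locus.genes]
    groups: Dict[Tuple[str, str], List[int]] = {}
    for idx, gid in enumerate(order):
        best = ortholog_best.get(gid)
        if not best:
            continue
        for model_tag, (subject_id, _ident) in best.items():
            groups.setdefault((model_tag, subject_id), []).append(idx)
    claimed: Dict[str, str] = {}
    for (model_tag, subject_id), idxs in sorted(groups.items()):
        if len(idxs) < 2:
            continue
        idxs = sorted(idxs)
        # split into adjacency runs
        runs: List[List[int]] = [[idxs[0]]]
        for i in idxs[1:]:
            if i - runs[-1][-1] <= max_intervening + 1:
                runs[-1].append(i)
            else:
                runs.append([i])
        for run in runs:
            if len(run) < 2:
                continue
            def key(i: int) -> Tuple[float, int]:
                gid = order[i]
                ident = ortholog_best[gid][model_tag][1]
                return (-ident, i)  # best identity, tie -> 5'-most
            keeper = min(run, key=key)
            for i in run:
                if i == keeper:
                    continue
                gid = order[i]
                prof = prof_by_id.get(gid)
                if prof is None or prof.category == "EXCLUDED":
                    continue
                if gid in claimed:
                    continue
                prof.category = "TANDEM_DUP_NC"
                prof.tandem_partner = order[keeper]
                claimed[gid] = order[keeper]
    return profiles


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def summarize_collinearity(
    profiles: Sequence[CollinearityProfile],
    wheat_tags: Tuple[str, str] = ("3DS", "3B"),
) -> pd.DataFrame:
    """Per-genome counts and percentages (one decimal, round half up).

    The homoeolog percentage keeps EXCLUDED genes in the denominator and is
    reported as a whole percent; the per-locus "specific" count pools
    LOCUS_SPECIFIC_NC and TANDEM_DUP_NC copies (genes with no reciprocal
    wheat-wheat pair).
    """
    if not profiles:
        return pd.DataFrame(
            columns=[
                "genome", "n_genes", "n_collinear", "pct_collinear", "n_shared_nc",
                "n_specific", "n_tandem", "n_excluded", "n_pairs", "pct_homoeolog",
            ]
        )
    rows = []
    by_genome: Dict[str, List[CollinearityProfile]] = {}
    for p in profiles:
        by_genome.setdefault(p.genome_tag, []).append(p)
    d_tag, b_tag = wheat_tags
    for genome, profs in by_genome.items():
        n = len(profs)
        counts = {c: sum(1 for p in profs if p.category == c) for c in CATEGORIES}
        n_coll = counts["COLLINEAR_ALL"] + counts["COLLINEAR_RICE_WHEAT"]
        other = d_tag if genome == b_tag else b_tag
        n_pairs = sum(
            1 for p in profs if p.homologs.get(other, (None, 0.0))[0] is not None
        ) if genome in wheat_tags else 0
        rows.append(
            {
                "genome": genome,
                "n_genes": n,
                "n_collinear": n_coll,
                "pct_collinear": round_half_up(100.0 * n_coll / n, 1) if n else 0.0,
                "n_shared_nc": counts["SHARED_WHEAT_NC"],
                "n_specific": counts["LOCUS_SPECIFIC_NC"] + counts["TANDEM_DUP_NC"],
                "n_tandem": counts["TANDEM_DUP_NC"],
                "n_excluded": counts["EXCLUDED"],
                "n_pairs": n_pairs,
                "pct_homoeolog": round_half_up(100.0 * n_pairs / n, 0) if genome in wheat_tags and n else 0.0,
            }
        )
    return pd.DataFrame(rows)


def gene_distances(locus: LocusAnnotation) -> Tuple[float, float, List[int]]:
    """Mean/median/list of consecutive inter-gene distances (end to next start)."""
    if len(locus.genes) < 2:
        raise ValueError(f"locus {locus.locus_id}: need >= 2 genes for distance statistics")
    dists = [
        nxt.span.start - cur.span.end
        for cur, nxt in zip(locus.genes, locus.genes[1:])
    ]
    s = sorted(dists)
    n = len(s)
    median = float(s[n // 2]) if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2.0
    return sum(dists) / n, median, dists


def repeat_composition(repeats: Sequence[RepeatFeature]) -> pd.DataFrame:
    """Element counts, cumulative lengths and percent of total repeat length
    per (class, order, superfamily), one decimal."""
    rows = []
    total = sum(len(r.span) for r in repeats)
    agg: Dict[Tuple[str, str, str], List[int]] = {}
    for r in repeats:
        key = (r.rclass, r.order, r.superfamily)
        cur = agg.setdefault(key, [0, 0])
        cur[0] += 1
        cur[1] += len(r.span)
    for (rclass, order, superfamily), (count, length) in sorted(agg.items()):
        rows.append(
            {
                "class": rclass,
                "order": order,
                "superfamily": superfamily,
                "n_elements": count,
                "cumulative_length": length,
                "pct_of_repeats": round_half_up(100.0 * length / total, 1) if total else 0.0,
            }
        )
    return pd.DataFrame(rows)
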