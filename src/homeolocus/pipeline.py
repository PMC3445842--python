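"""End-to-end orchestration: homology maps, chains, classification, tandem
resolution, pseudogene census, epochs/rates, expression and promoter
scoring, starting from four annotated loci (wheat 3DS and 3B plus the
orthologous Brachypodium and rice regions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from . import collinearity as coll
from . import expression as expr
from . import pseudogene as pg
from . import rates as rates_mod
from .homology import (
    HomologyHit,
    best_map_from_table,
    mutual_best_from_table,
    score_table,
)
from .model import LocusAnnotation, SequenceRecord, extract_cds, upstream_region
from .params import AnalysisParams, DEFAULT_PARAMS


@dataclass
class PipelineResult:
    loci: Dict[str, LocusAnnotation]
    pairs: Dict[Tuple[str, str], List[Tuple[str, str, float]]]
    profiles: List[coll.CollinearityProfile]
    summary: pd.DataFrame
    pseudo_calls: Dict[str, pg.PseudogeneCall]
    mechanisms: Dict[str, str]
    census: pd.DataFrame
    epochs: List[rates_mod.EpochAssignment]
    rate_ratio: Optional[rates_mod.RateRatio]
    est_hits: List[expr.ESTHit] = field(default_factory=list)
    removed_ests: List[str] = field(default_factory=list)
    expression: Optional[pd.DataFrame] = None
    promoter_calls: List[expr.PromoterCall] = field(default_factory=list)
    promoters: Optional[pd.DataFrame] = None

    @property
    def wheat_pairs(self) -> List[Tuple[str, str, float]]:
        return self.pairs[("3DS", "3B")]


def _cds_records(locus: LocusAnnotation, include_excluded: bool = False) -> List[SequenceRecord]:
    out = []
    for gene in locus.genes:
        if gene.status == "excluded" and not include_excluded:
            continue
        out.append(SequenceRecord(id=gene.id, residues=extract_cds(locus, gene, allow_n=True)))
    return out


def run_pipeline(
    loci: Sequence[LocusAnnotation],
    ests: Optional[Sequence[SequenceRecord]] = None,
    params: AnalysisParams = DEFAULT_PARAMS,
    reference_db: Optional[Sequence[SequenceRecord]] = None,
    wheat_tags: Tuple[str, str] = ("3DS", "3B"),
    brachy_tag: str = "Bd2",
    rice_tag: str = "Os1",
    scan_promoters: bool = True,
) -> PipelineResult:
    by_tag = {locus.genome_tag: locus for locus in loci}
    d_tag, b_tag = wheat_tags
    for tag in (d_tag, b_tag):
        if tag not in by_tag:
            raise ValueError(f"missing wheat locus {tag!r}")
    model_tags = [t for t in (brachy_tag, rice_tag) if t in by_tag]

    cds: Dict[str, List[SequenceRecord]] = {tag: _cds_records(by_tag[tag]) for tag in by_tag}

    # --- one exact all-vs-all scoring pass per locus pair involving wheat ---
    locus_pairs = [(d_tag, b_tag)] + [(w, m) for w in (d_tag, b_tag) for m in model_tags]
    tables = {key: score_table(cds[key[0]], cds[key[1]], params) for key in locus_pairs}

    # reciprocal-best pairing
    pair_maps: Dict[Tuple[str, str], Dict[str, Tuple[str, float]]] = {}
    pair_lists: Dict[Tuple[str, str], List[Tuple[str, str, float]]] = {}
    for key in locus_pairs:
        mutual = mutual_best_from_table(tables[key], params)
        pair_maps[key] = {a: (b, ident) for a, b, ident in mutual}
        pair_maps[(key[1], key[0])] = {b: (a, ident) for a, b, ident in mutual}
        pair_lists[key] = mutual

    # best-hit maps of wheat genes onto the model genomes (including
    # non-reciprocal hits; needed to group tandem copies with their source)
    ortholog_best: Dict[str, Dict[str, Dict[str, Tuple[str, float]]]] = {d_tag: {}, b_tag: {}}
    for wtag in (d_tag, b_tag):
        for mtag in model_tags:
            for qid, (sid, identity) in best_map_from_table(tables[(wtag, mtag)], params).items():
                ortholog_best[wtag].setdefault(qid, {})[mtag] = (sid, identity)

    # --- anchor chains over gene order ---
    chains: Dict[Tuple[str, str], set] = {}
    for tag_a, tag_b in locus_pairs:
        order_a = {g.id: i for i, g in enumerate(by_tag[tag_a].genes)}
        order_b = {g.id: i for i, g in enumerate(by_tag[tag_b].genes)}
        anchors = []
        id_by_index = {}
        for a_id, b_id, identity in pair_lists[(tag_a, tag_b)]:
            ia, ib = order_a[a_id], order_b[b_id]
            anchors.append((ia, ib, identity))
            id_by_index[(ia, ib)] = (a_id, b_id)
        chain = coll.chain_anchors(anchors)
        chains[(tag_a, tag_b)] = {id_by_index[a] for a in chain.anchors}

    # --- classification and tandem resolution ---
    profiles = coll.classify_genes(
        by_tag, pair_maps, chains, wheat_tags=wheat_tags, brachy_tag=brachy_tag, rice_tag=rice_tag
    )
    for wtag in (d_tag, b_tag):
        coll.resolve_tandem(
            by_tag[wtag], profiles, ortholog_best[wtag], max_intervening=params.tandem_max_intervening
        )
    summary = coll.summarize_collinearity(profiles, wheat_tags=wheat_tags)

    # --- pseudogene assessment ---
    cds_by_id: Dict[str, str] = {}
    locus_of: Dict[str, str] = {}
    for tag, records in cds.items():
        for rec in records:
            cds_by_id[rec.id] = rec.residues
            locus_of[rec.id] = tag
    ref_records = {r.id: r.residues for r in (reference_db or [])}

    # within-locus homology (a tandem copy's closest intact homolog is its
    # own adjacent source gene, a far better reference than a model ortholog)
    self_best: Dict[str, Dict[str, Tuple[str, float]]] = {}
    for wtag in (d_tag, b_tag):
        table = score_table(cds[wtag], cds[wtag], params)
        table = {k: v for k, v in table.items() if k[0] != k[1]}
        self_best[wtag] = best_map_from_table(table, params)

    def intact_reference(gene_id: str, wtag: str) -> Optional[Tuple[str, str]]:
        other = b_tag if wtag == d_tag else d_tag
        partner = pair_maps.get((wtag, other), {}).get(gene_id)
        if partner and pg.orf_is_valid(cds_by_id[partner[0]]):
            return partner[0], cds_by_id[partner[0]]
        sibling = self_best[wtag].get(gene_id)
        if sibling and pg.orf_is_valid(cds_by_id[sibling[0]]):
            return sibling[0], cds_by_id[sibling[0]]
        for mtag in model_tags:
            ortholog = pair_maps.get((wtag, mtag), {}).get(gene_id)
            if ortholog and pg.orf_is_valid(cds_by_id[ortholog[0]]):
                return ortholog[0], cds_by_id[ortholog[0]]
        best = ortholog_best[wtag].get(gene_id)
        if best:
            for mtag, (sid, _ident) in sorted(best.items()):
                if pg.orf_is_valid(cds_by_id[sid]):
                    return sid, cds_by_id[sid]
        if ref_records:
            from .homology import find_best_homolog

            hit = find_best_homolog(
                SequenceRecord(id=gene_id, residues=cds_by_id[gene_id]),
                [SequenceRecord(id=rid, residues=rseq) for rid, rseq in sorted(ref_records.items())],
                params,
            )
            if hit and pg.orf_is_valid(ref_records[hit.subject_id]):
                return hit.subject_id, ref_records[hit.subject_id]
        return None

    pseudo_calls: Dict[str, pg.PseudogeneCall] = {}
    for wtag in (d_tag, b_tag):
        for gene in by_tag[wtag].genes:
            if gene.status == "excluded":
                continue
            ref = intact_reference(gene.id, wtag)
            if ref is None:
                continue
            ref_id, ref_cds = ref
            pseudo_calls[gene.id] = pg.assess_integrity(
                cds_by_id[gene.id], ref_cds, params, gene_id=gene.id, homolog_id=ref_id
            )

    # reconcile within homoeologous pairs: a "deletion" called against a
    # partner that is itself shorter reflects an incomplete reference (the
    # partner carries the deletion), not a defect of the longer copy
    for d_id, b_id, _ident in pair_lists[(d_tag, b_tag)]:
        for x, y in ((d_id, b_id), (b_id, d_id)):
            cx = pseudo_calls.get(x)
            if (
                cx is not None
                and cx.status != "intact"
                and cx.homolog_id == y
                and cx.defects
                and all(d.kind == "deletion" for d in cx.defects)
                and len(cds_by_id[x]) > len(cds_by_id[y])
            ):
                pseudo_calls[x] = pg.PseudogeneCall(
                    gene_id=x, status="intact", homolog_id=y, coverage=cx.coverage
                )
    census = pg.pseudogene_census(pseudo_calls, profiles)

    # --- mechanism attribution for wheat gene-pseudogene pairs ---
    mechanisms: Dict[str, str] = {}
    flank = params.upstream_len
    for d_id, b_id, _ident in pair_lists[(d_tag, b_tag)]:
        call_d = pseudo_calls.get(d_id)
        call_b = pseudo_calls.get(b_id)
        for intact_id, broken_id, intact_tag, broken_tag in (
            (d_id, b_id, d_tag, b_tag),
            (b_id, d_id, b_tag, d_tag),
        ):
            call = pseudo_calls.get(broken_id)
            other_call = pseudo_calls.get(intact_id)
            if not call or call.status not in ("pseudogene", "fragment"):
                continue
            if other_call and other_call.status != "intact":
                continue
            intact_locus = by_tag[intact_tag]
            broken_locus = by_tag[broken_tag]
            gi = intact_locus.gene(intact_id)
            gb = broken_locus.gene(broken_id)
            g0 = max(0, gi.span.start - flank)
            g1 = min(len(intact_locus.sequence), gi.span.end + flank)
            p0 = max(0, gb.span.start - flank)
            p1 = min(len(broken_locus.sequence), gb.span.end + flank)
            gene_region = intact_locus.sequence.residues[g0:g1]
            pseudo_region = broken_locus.sequence.residues[p0:p1]
            exons = [coll_span_shift(e, -g0) for e in gi.exons]
            repeats = [
                coll_span_shift(r.span, -p0)
                for r in broken_locus.repeats
                if r.span.start < p1 and p0 < r.span.end
            ]
            mechanisms[broken_id] = pg.attribute_mechanism(
                gene_region, pseudo_region, repeats, exons, params
            )
            if broken_id in pseudo_calls:
                pseudo_calls[broken_id].mechanism = mechanisms[broken_id]

    # --- epochs and rate ratio ---
    epochs = rates_mod.assign_epochs(profiles, params)
    wheat_epochs = [e for e in epochs if e.genome_tag in wheat_tags]
    n_int = sum(1 for e in wheat_epochs if e.genome_tag == d_tag and e.epoch == "INTERMEDIATE")
    n_rec = sum(1 for e in wheat_epochs if e.epoch == "RECENT")
    rate_ratio = rates_mod.insertion_rate_ratio(
        n_int, n_rec, params.t_old, params.t_bd_split_range
    ) if (n_int or n_rec) else None

    result = PipelineResult(
        loci=by_tag,
        pairs=pair_lists,
        profiles=profiles,
        summary=summary,
        pseudo_calls=pseudo_calls,
        mechanisms=mechanisms,
        census=census,
        epochs=epochs,
        rate_ratio=rate_ratio,
    )

    # --- expression ---
    if ests is not None:
        wheat_cds = cds[d_tag] + cds[b_tag]
        hits = expr.match_ests(wheat_cds, ests, params)
        pairs_ab = [(a, b) for a, b, _ in pair_lists[(d_tag, b_tag)]]
        kept, removed = expr.drop_shared_ests(hits, pairs_ab)
        result.est_hits = kept
        result.removed_ests = removed
        result.expression = expr.expression_summary(kept, profiles, wheat_tags=wheat_tags)

    # --- promoter scan ---
    if scan_promoters:
        calls = []
        for wtag in (d_tag, b_tag):
            locus = by_tag[wtag]
            for gene in locus.genes:
                if gene.status == "excluded":
                    continue
                region = upstream_region(locus, gene, params.upstream_len)
                calls.append(expr.scan_promoter(region.sequence, params, gene_id=gene.id))
        result.promoter_calls = calls
        result.promoters = expr.promoter_summary(calls, profiles, wheat_tags=wheat_tags)
    return result


def coll_span_shift(span, offset: int):
    from .model import Span

    return Span(span.start + offset, span.end + offset)
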