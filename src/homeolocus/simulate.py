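"""Locus-evolution simulator, EST generator and BAC-pool fixture builder.

``simulate_locus_evolution`` evolves four loci (rice Os1, Brachypodium Bd2,
wheat 3B and 3DS) from one ancestral gene layout along a fixed species
tree: rice and Brachypodium split from the wheat lineage at
``t_brachy_split`` (MYA), the wheat B and D progenitors split at
``t_bd_split``.  Gene insertions, deletions, tandem duplications and
pseudogenizations are Poisson processes per lineage; insertion rates are
multiplied by ``acceleration`` after the B/D split.  Every event is logged
with its time and lineage, so downstream classification can be checked
against the ground truth.  Substitution divergence is uniform per site and
MY; intergenic spacers are lineage-independent (TE turnover erases
intergenic homology on these timescales) and B-lineage spacers are
expanded by ``te_expansion_factor_B``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from ._seqgen import mutate, random_dna, random_orf
from .expression import _maximal_exact_matches
from .model import (
    GeneModel,
    LocusAnnotation,
    RepeatFeature,
    SequenceRecord,
    Span,
    extract_cds,
)
from .params import AnalysisParams, DEFAULT_PARAMS
from .pooling import PoolDesign, ScreenResult, design_pools

MECHANISMS = ("TE_INSERTION", "POINT_FRAMESHIFT", "INTERNAL_DELETION", "TERMINAL_TRUNCATION")

MAX_GENES = 10_000


@dataclass
class SimParams:
    t_brachy_split: float = 35.0
    t_bd_split: Optional[float] = None       # drawn from t_bd_split_range when None
    t_bd_split_range: Tuple[float, float] = (2.5, 4.5)
    t_barley_split: Optional[float] = None   # optional lineage, off by default
    t_tetraploid: float = 0.5
    insertion_rate: float = 0.57             # events / MY / locus (pre-split epoch)
    acceleration: float = 3.0                # insertion fold-change after the B/D split
    deletion_rate: float = 0.02
    tandem_dup_rate: float = 0.05
    pseudogenization_rate: float = 0.05
    te_expansion_factor_B: float = 0.27
    subst_rate: float = 0.002                # substitutions / site / MY
    n_ancestral_genes: int = 15
    gene_codon_range: Tuple[int, int] = (150, 350)
    intergenic_median: float = 17_700.0      # bp; lognormal spacer lengths
    intergenic_sigma: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("insertion_rate", "deletion_rate", "tandem_dup_rate",
                     "pseudogenization_rate", "subst_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.t_bd_split_range
        t_bd = self.t_bd_split if self.t_bd_split is not None else hi
        if not self.t_brachy_split > t_bd > self.t_tetraploid:
            raise ValueError("times must satisfy t_brachy_split > t_bd_split > t_tetraploid")


@dataclass
class Event:
    time: float       # MYA
    lineage: str      # wheat_stem | 3B | 3DS | Bd2 | Os1
    kind: str         # insert | delete | tandem_dup | pseudogenize:<mechanism>
    gene_id: str      # family-level id; resolves to "<genome_tag>:<family>" gene ids


@dataclass
class EventLog:
    events: List[Event] = field(default_factory=list)
    t_bd_split: float = 0.0

    def count(self, kind_prefix: str, lineage: Optional[str] = None) -> int:
        return sum(
            1
            for e in self.events
            if e.kind.startswith(kind_prefix) and (lineage is None or e.lineage == lineage)
        )

    def insertions_by_epoch(self) -> Dict[str, int]:
        """INTERMEDIATE: wheat-stem insertions; RECENT: per wheat-locus insertions."""
        out = {"INTERMEDIATE": 0, "RECENT_3DS": 0, "RECENT_3B": 0}
        for e in self.events:
            if e.kind != "insert":
                continue
            if e.lineage == "wheat_stem":
                out["INTERMEDIATE"] += 1
            elif e.lineage in ("3DS", "3B"):
                out[f"RECENT_{e.lineage}"] += 1
        return out


@dataclass
class _SimGene:
    family: str
    cds: str
    status: str = "intact"          # intact | pseudogene
    mechanism: Optional[str] = None
    te_interval: Optional[Tuple[int, int]] = None  # CDS coords of an inserted TE
    birth_time: Optional[float] = None  # MYA; None = ancestral


def _evolve_branch(
    genes: List[_SimGene],
    t_start: float,
    t_end: float,
    lineage: str,
    params: SimParams,
    rng: np.random.Generator,
    log: EventLog,
    counter: List[int],
    accelerate: bool,
) -> List[_SimGene]:
    duration = t_start - t_end
    genes = [replace(g) for g in genes]
    ins_rate = params.insertion_rate * (params.acceleration if accelerate else 1.0)
    kinds = {
        "insert": ins_rate,
        "delete": params.deletion_rate,
        "tandem_dup": params.tandem_dup_rate,
        "pseudogenize": params.pseudogenization_rate,
    }
    schedule: List[Tuple[float, str]] = []
    for kind, rate in kinds.items():
        n = rng.poisson(rate * duration)
        for t in rng.uniform(t_end, t_start, size=n):
            schedule.append((t, kind))
    schedule.sort(reverse=True)  # oldest (largest MYA) first

    for t, kind in schedule:
        if kind == "insert":
            counter[0] += 1
            fam = f"ins{counter[0]:04d}"
            n_codons = int(rng.integers(*params.gene_codon_range))
            gene = _SimGene(family=fam, cds=random_orf(rng, n_codons), birth_time=t)
            pos = int(rng.integers(0, len(genes) + 1))
            genes.insert(pos, gene)
            log.events.append(Event(time=t, lineage=lineage, kind="insert", gene_id=fam))
        elif kind == "delete":
            if not genes:
                continue
            pos = int(rng.integers(0, len(genes)))
            gone = genes.pop(pos)
            log.events.append(Event(time=t, lineage=lineage, kind="delete", gene_id=gone.family))
        elif kind == "tandem_dup":
            if not genes:
                continue
            pos = int(rng.integers(0, len(genes)))
            src = genes[pos]
            counter[0] += 1
            fam = f"{src.family}.td{counter[0]:04d}"
            copy = replace(src, family=fam, birth_time=t)
            # the new copy starts diverging immediately; give it a small
            # burst so best-homolog choices are not coin flips
            copy.cds = mutate(rng, copy.cds, 0.005, preserve_orf=src.status == "intact")
            genes.insert(pos + 1, copy)
            log.events.append(Event(time=t, lineage=lineage, kind="tandem_dup", gene_id=fam))
        else:  # pseudogenize
            intact = [g for g in genes if g.status == "intact"]
            if not intact:
                continue
            target = intact[int(rng.integers(0, len(intact)))]
            mech = MECHANISMS[int(rng.integers(0, len(MECHANISMS)))]
            _apply_defect(target, mech, rng)
            log.events.append(
                Event(time=t, lineage=lineage, kind=f"pseudogenize:{mech}", gene_id=target.family)
            )
        if len(genes) > MAX_GENES:
            raise ValueError(f"simulated locus exceeds {MAX_GENES} genes; lower the rates")

    # substitution divergence along the branch
    frac = min(0.75, params.subst_rate * duration)
    for g in genes:
        protect = None
        if g.te_interval:
            protect = set(range(*g.te_interval))
        g.cds = mutate(rng, g.cds, frac, protect=protect, preserve_orf=g.status == "intact")
    return genes


def _apply_defect(gene: _SimGene, mechanism: str, rng: np.random.Generator) -> None:
    cds = gene.cds
    n = len(cds)
    if mechanism == "TE_INSERTION":
        te_len = 100  # 100 % 3 == 1: frameshifting, like most real insertions
        pos = int(rng.integers(int(n * 0.7), n - 3))  # into the last portion of the CDS
        te = random_dna(rng, te_len)
        gene.cds = cds[:pos] + te + cds[pos:]
        gene.te_interval = (pos, pos + te_len)
    elif mechanism == "POINT_FRAMESHIFT":
        pos = int(rng.integers(n // 4, 3 * n // 4))
        gene.cds = cds[:pos] + random_dna(rng, 1) + cds[pos:]
    elif mechanism == "INTERNAL_DELETION":
        del_len = max(30, int(n * 0.35) // 3 * 3)
        start = int(rng.integers(n // 6, n - del_len - n // 6))
        gene.cds = cds[:start] + cds[start + del_len:]
    elif mechanism == "TERMINAL_TRUNCATION":
        keep = max(60, int(n * 0.45))
        gene.cds = cds[n - keep:]
    else:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    gene.status = "pseudogene"
    gene.mechanism = mechanism


def _emit_locus(
    tag: str,
    genes: Sequence[_SimGene],
    params: SimParams,
    rng: np.random.Generator,
) -> LocusAnnotation:
    expand = 1.0 + params.te_expansion_factor_B if tag == "3B" else 1.0
    parts: List[str] = []
    models: List[GeneModel] = []
    repeats: List[RepeatFeature] = []
    pos = 0
    mu = float(np.log(params.intergenic_median))
    for g in genes:
        spacer_len = int(expand * float(rng.lognormal(mu, params.intergenic_sigma)))
        spacer_len = max(200, spacer_len)
        parts.append(random_dna(rng, spacer_len))
        pos += spacer_len
        start = pos
        parts.append(g.cds)
        pos += len(g.cds)
        span = Span(start, pos)
        models.append(
            GeneModel(
                id=f"{tag}:{g.family}",
                locus_id=tag,
                strand="+",
                span=span,
                exons=[span],
                status="pseudogene" if g.status == "pseudogene" else "intact",
                notes=[f"family:{g.family}"],
            )
        )
        if g.te_interval:
            t0, t1 = g.te_interval
            repeats.append(
                RepeatFeature(
                    span=Span(start + t0, start + t1),
                    rclass="DNA_transposon",
                    order="TIR",
                    superfamily="CACTA",
                    complete=True,
                )
            )
    parts.append(random_dna(rng, max(200, int(expand * float(rng.lognormal(mu, params.intergenic_sigma))))))
    sequence = SequenceRecord(id=tag, residues="".join(parts))
    return LocusAnnotation(locus_id=tag, genome_tag=tag, sequence=sequence, genes=models, repeats=repeats)


def simulate_locus_evolution(params: SimParams) -> Tuple[List[LocusAnnotation], EventLog]:
    """Simulate four loci descending from one ancestral layout.

    Returns loci in the order (3DS, 3B, Bd2, Os1) plus the event log; a
    fixed seed gives byte-identical output.
    """
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    t_bd = params.t_bd_split
    if t_bd is None:
        lo, hi = params.t_bd_split_range
        t_bd = float(rng.uniform(lo, hi))
    log = EventLog(t_bd_split=t_bd)
    counter = [0]

    ancestral = [
        _SimGene(family=f"fam{i:03d}", cds=random_orf(rng, int(rng.integers(*params.gene_codon_range))))
        for i in range(params.n_ancestral_genes)
    ]

    os_genes = _evolve_branch(ancestral, params.t_brachy_split, 0.0, "Os1", params, rng, log, counter, False)
    bd_genes = _evolve_branch(ancestral, params.t_brachy_split, 0.0, "Bd2", params, rng, log, counter, False)
    stem = _evolve_branch(ancestral, params.t_brachy_split, t_bd, "wheat_stem", params, rng, log, counter, False)
    b_genes = _evolve_branch(stem, t_bd, 0.0, "3B", params, rng, log, counter, True)
    d_genes = _evolve_branch(stem, t_bd, 0.0, "3DS", params, rng, log, counter, True)

    loci = [
        _emit_locus("3DS", d_genes, params, rng),
        _emit_locus("3B", b_genes, params, rng),
        _emit_locus("Bd2", bd_genes, params, rng),
        _emit_locus("Os1", os_genes, params, rng),
    ]
    return loci, log


# ---------------------------------------------------------------------------
# EST generation
# ---------------------------------------------------------------------------

def generate_ests(
    loci: Sequence[LocusAnnotation],
    expression_truth: Dict[str, bool],
    n_per_expressed: int = 2,
    error_rate: float = 0.0,
    seed: int = 0,
    params: AnalysisParams = DEFAULT_PARAMS,
    shared_pairs: Optional[Sequence[Tuple[str, str]]] = None,
    n_decoys: int = 0,
    est_len_range: Tuple[int, int] = (130, 200),
) -> List[SequenceRecord]:
    """Synthesize an EST collection matching an expression ground truth.

    Every expressed gene receives ``n_per_expressed`` ESTs, each an exact
    CDS substring of at least ``est_min_len`` bases chosen (by rejection)
    to match no other gene, so expression calls are unambiguous.  Each pair
    in ``shared_pairs`` additionally receives one EST matching an identical
    window of both members (these are the ESTs the shared-EST filter must
    remove).  ``n_decoys`` non-expressed genes receive below-threshold
    decoys: one exact match shorter than ``est_min_len`` and one long match
    broken by a central mismatch.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    cds_by_gene: Dict[str, str] = {}
    for locus in loci:
        for gene in locus.genes:
            if gene.status == "excluded":
                continue
            cds_by_gene[gene.id] = extract_cds(locus, gene, allow_n=True)

    from .expression import _INDEX_K, _kmer_index

    indexes = {gid: _kmer_index(c) for gid, c in cds_by_gene.items()} \
        if params.est_min_len >= _INDEX_K else {}

    def n_matches(seq: str) -> Set[str]:
        found = set()
        for gid, cds in cds_by_gene.items():
            if _maximal_exact_matches(seq, cds, params.est_min_len, indexes.get(gid)):
                found.add(gid)
        return found

    ests: List[SequenceRecord] = []
    counter = 0

    for gid in sorted(g for g, expr in expression_truth.items() if expr):
        cds = cds_by_gene.get(gid)
        if cds is None:
            raise KeyError(f"expression truth names unknown gene {gid!r}")
        if len(cds) < params.est_min_len:
            warnings.warn(f"gene {gid}: CDS shorter than est_min_len, skipped")
            continue
        made = 0
        attempts = 0
        while made < n_per_expressed and attempts < 200:
            attempts += 1
            length = int(rng.integers(*est_len_range))
            length = min(length, len(cds))
            start = int(rng.integers(0, len(cds) - length + 1))
            piece = cds[start:start + length]
            if error_rate > 0:
                piece = mutate(rng, piece, error_rate)
            if n_matches(piece) != {gid}:
                continue
            counter += 1
            rec = SequenceRecord(id=f"EST{counter:05d}", residues=piece, description=f"src:{gid}")
            if rng.random() < 0.5:  # EST orientations are arbitrary
                from .model import reverse_complement

                rec = SequenceRecord(id=rec.id, residues=reverse_complement(piece), description=rec.description)
            ests.append(rec)
            made += 1
        if made < n_per_expressed:
            warnings.warn(f"gene {gid}: no distinctive EST window found")

    for a_id, b_id in shared_pairs or ():
        shared = _maximal_exact_matches(cds_by_gene[a_id], cds_by_gene[b_id], params.est_min_len)
        if not shared:
            raise ValueError(f"pair ({a_id}, {b_id}) shares no exact window >= est_min_len")
        a0, b0, length = max(shared, key=lambda m: m[2])
        piece = cds_by_gene[a_id][a0:a0 + length]
        if n_matches(piece) != {a_id, b_id}:
            raise ValueError(f"shared window of ({a_id}, {b_id}) is not pair-specific")
        counter += 1
        ests.append(
            SequenceRecord(id=f"EST{counter:05d}", residues=piece, description=f"shared:{a_id}|{b_id}")
        )

    unexpressed = sorted(g for g, expr in expression_truth.items() if not expr and g in cds_by_gene)
    for gid in unexpressed[:n_decoys]:
        cds = cds_by_gene[gid]
        if len(cds) < params.est_min_len + 60:
            continue
        # short exact decoy (below the length threshold)
        short_len = params.est_min_len - 20
        start = int(rng.integers(0, len(cds) - short_len + 1))
        counter += 1
        ests.append(
            SequenceRecord(id=f"EST{counter:05d}", residues=cds[start:start + short_len],
                           description=f"decoy_short:{gid}")
        )
        # long decoy broken by a central mismatch (identity < 100%)
        long_len = params.est_min_len + 50
        start = int(rng.integers(0, len(cds) - long_len + 1))
        piece = list(cds[start:start + long_len])
        mid = long_len // 2
        piece[mid] = {"A": "C", "C": "A", "G": "T", "T": "G"}[piece[mid]]
        piece = "".join(piece)
        if n_matches(piece):
            continue
        counter += 1
        ests.append(SequenceRecord(id=f"EST{counter:05d}", residues=piece, description=f"decoy_mm:{gid}"))
    return ests


# ---------------------------------------------------------------------------
# BAC pool fixture
# ---------------------------------------------------------------------------

@dataclass
class PoolFixture:
    design: PoolDesign
    screens: List[ScreenResult]
    screen_table: pd.DataFrame
    marker_truth: Dict[str, List[str]]
    clone_to_contig: Dict[str, str]


def build_pool_fixture(
    n_clones: int = 3827,
    plates: int = 10,
    rows: int = 16,
    cols: int = 24,
    marker_truth: Optional[Dict[str, List[str]]] = None,
    seed: int = 0,
    n_contigs: int = 8,
) -> PoolFixture:
    """A screened 3-D pool set with known marker-to-clone truth.

    Default markers mirror the screening structure of the study: twelve
    EST-derived markers, four hitting a single clone each, eight hitting
    two clones; five of the two-clone markers bridge different physical-map
    contigs over three distinct contig pairs, one pair supported by three
    markers.
    """
    capacity = plates * rows * cols
    if n_clones > capacity:
        raise ValueError(f"{n_clones} clones exceed capacity {capacity}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    clones = [f"BAC{i:04d}" for i in range(1, n_clones + 1)]
    design = design_pools(clones, plates, rows, cols)

    bounds = np.linspace(0, n_clones, n_contigs + 1).astype(int)
    clone_to_contig = {}
    for ci in range(n_contigs):
        for clone in clones[bounds[ci]:bounds[ci + 1]]:
            clone_to_contig[clone] = f"ctg{ci + 1}"

    if marker_truth is None:
        def pick(contig: str) -> str:
            members = [c for c in clones if clone_to_contig[c] == contig]
            return members[int(rng.integers(0, len(members)))]

        marker_truth = {}
        for i in range(1, 5):  # single-clone markers
            marker_truth[f"m{i:02d}"] = [pick(f"ctg{i}")]
        cross = [("ctg1", "ctg2"), ("ctg1", "ctg2"), ("ctg1", "ctg2"),
                 ("ctg3", "ctg4"), ("ctg5", "ctg6")]
        for i, (ca, cb) in enumerate(cross, start=5):  # cross-contig doubles
            marker_truth[f"m{i:02d}"] = sorted({pick(ca), pick(cb)})
        for i in range(10, 13):  # within-contig doubles
            contig = f"ctg{min(i - 4, n_contigs)}"
            a = pick(contig)
            b = pick(contig)
            while b == a:
                b = pick(contig)
            marker_truth[f"m{i:02d}"] = sorted([a, b])

    screens = []
    rows_out = []
    for marker, truth_clones in sorted(marker_truth.items()):
        screen = design.positive_pools(truth_clones)
        screen.marker_id = marker
        screens.append(screen)
        for dim, pools in (("plate", screen.plates), ("row", screen.rows), ("col", screen.cols)):
            for pool in pools:
                rows_out.append({"marker": marker, "dimension": dim, "pool": pool})
    return PoolFixture(
        design=design,
        screens=screens,
        screen_table=pd.DataFrame(rows_out),
        marker_truth=marker_truth,
        clone_to_contig=clone_to_contig,
    )
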