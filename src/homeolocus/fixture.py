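"""Deterministic four-locus fixture reproducing the printed count structure
of the comparative study.

The generator plants concrete sequences — it does not label anything for
the pipeline.  Homoeologous wheat copies sit at ~95% identity, wheat-to-
model-genome orthologs at ~85%; defective genes are built by literally
applying the four pseudogenization mechanisms (TE insertion into an exon,
single-nucleotide frameshift, internal deletion, 5' truncation); promoter
and EST ground truths are planted by motif insertion and exact-substring
sampling with rejection, so the downstream pipeline (homology ->
collinearity -> pseudogene -> expression) recovers every count from
sequence alone, for any seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from ._seqgen import mutate, random_dna, random_orf
from .expression import scan_promoter
from .model import (
    GeneModel,
    LocusAnnotation,
    RepeatFeature,
    SequenceRecord,
    Span,
)
from .params import AnalysisParams, DEFAULT_PARAMS
from .simulate import generate_ests

WHEAT_D = "3DS"
WHEAT_B = "3B"
BRACHY = "Bd2"
RICE = "Os1"


@dataclass
class FixtureSpec:
    """The printed count structure as named integers."""

    n_3DS: int = 39
    n_3B: int = 38
    n_pairs: int = 32
    n_collinear_all: int = 14
    n_collinear_rice_wheat: int = 1
    n_shared_nc: int = 17
    n_3DS_specific: int = 7
    n_3B_specific: int = 5
    n_3B_excluded: int = 1
    n_Bd: int = 22
    n_Os: int = 21
    tandem_3DS: int = 3
    tandem_3B: int = 2
    pseudo_3DS: int = 2
    pseudo_3B: int = 6
    pseudo_3B_noncollinear: int = 5
    n_expr_3DS_collinear: int = 8    # of 15 -> 53.3%
    n_expr_3DS_noncollinear: int = 10  # of 24 -> 41.7%
    n_expr_3B_collinear: int = 5     # of 15 -> 33.3%
    n_expr_3B_noncollinear: int = 5  # of 22 -> 22.7%
    n_prom_collinear: int = 11       # of 15 -> ~73%
    n_prom_3DS_noncollinear: int = 13  # of 24 -> 54.2%
    n_prom_3B_noncollinear: int = 12   # of 22 -> 54.5%
    shared_ests_removed: int = 4

    def validate(self) -> None:
        n_coll = self.n_collinear_all + self.n_collinear_rice_wheat
        if n_coll + self.n_shared_nc + self.n_3DS_specific != self.n_3DS:
            raise ValueError("3DS counts inconsistent: collinear + shared + specific != n_3DS")
        if n_coll + self.n_shared_nc + self.n_3B_specific + self.n_3B_excluded != self.n_3B:
            raise ValueError("3B counts inconsistent")
        if self.n_pairs != n_coll + self.n_shared_nc:
            raise ValueError("n_pairs must equal collinear + shared families")
        if self.tandem_3DS > self.n_3DS_specific or self.tandem_3B > self.n_3B_specific:
            raise ValueError("tandem copies exceed locus-specific counts")
        if self.n_Bd < self.n_collinear_all or self.n_Os < n_coll:
            raise ValueError("model-genome counts below collinear family counts")
        if self.tandem_3DS > self.n_collinear_all or self.tandem_3B > self.n_collinear_all:
            raise ValueError("tandem copies must duplicate collinear families")


@dataclass
class PaperFixture:
    loci: List[LocusAnnotation]          # 3DS, 3B, Bd2, Os1
    ests: List[SequenceRecord]
    reference_db: List[SequenceRecord]
    genes_truth: pd.DataFrame
    pairs_truth: pd.DataFrame
    shared_est_pairs: List[Tuple[str, str]]
    spec: FixtureSpec

    def locus(self, tag: str) -> LocusAnnotation:
        for l in self.loci:
            if l.genome_tag == tag:
                return l
        raise KeyError(tag)


@dataclass
class _FamilyGene:
    family: str
    kind: str                      # CA | CRW | SH | DS | DB | EXB | BD | OS | TD
    cds: str
    status: str = "intact"
    mechanism: Optional[str] = None
    two_exon: bool = False
    te_cds_interval: Optional[Tuple[int, int]] = None
    tandem_of: Optional[str] = None


def _interleave(primary: List, secondary: List) -> List:
    """Evenly merge two ordered lists (Bresenham-style), preserving order."""
    if not secondary:
        return list(primary)
    if not primary:
        return list(secondary)
    out = []
    np_, ns = len(primary), len(secondary)
    ip = is_ = 0
    total = np_ + ns
    for k in range(total):
        # place items proportionally to their progress
        if ip < np_ and (is_ >= ns or ip * ns <= is_ * np_):
            out.append(primary[ip])
            ip += 1
        else:
            out.append(secondary[is_])
            is_ += 1
    return out


def _insert_evenly(order: List, items: List) -> List:
    """Insert ``items`` at evenly spaced interior positions of ``order``."""
    out = list(order)
    if not items:
        return out
    step = max(1, len(out) // (len(items) + 1))
    pos = step
    for item in items:
        pos = min(pos, len(out))
        out.insert(pos, item)
        pos += step + 1
    return out


def build_paper_fixture(
    spec: Optional[FixtureSpec] = None,
    seed: int = 0,
    params: AnalysisParams = DEFAULT_PARAMS,
) -> PaperFixture:
    spec = spec or FixtureSpec()
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 20120830]))

    n_ca = spec.n_collinear_all
    n_crw = spec.n_collinear_rice_wheat
    n_sh = spec.n_shared_nc
    ca_names = [f"CA{i + 1:02d}" for i in range(n_ca)]
    crw_names = [f"CRW{i + 1:02d}" for i in range(n_crw)]
    sh_names = [f"SH{i + 1:02d}" for i in range(n_sh)]
    ds_names = [f"DS{i + 1:02d}" for i in range(spec.n_3DS_specific - spec.tandem_3DS)]
    db_names = [f"DB{i + 1:02d}" for i in range(spec.n_3B_specific - spec.tandem_3B)]
    exb_names = [f"EXB{i + 1:02d}" for i in range(spec.n_3B_excluded)]
    bd_names = [f"BDX{i + 1:02d}" for i in range(spec.n_Bd - n_ca)]
    os_names = [f"OSX{i + 1:02d}" for i in range(spec.n_Os - n_ca - n_crw)]

    # --- roles (the study's pseudogene structure) ---
    default_pseudo_structure = (
        spec.pseudo_3DS == 2 and spec.pseudo_3B == 6 and spec.pseudo_3B_noncollinear == 5
        and spec.tandem_3DS >= 1 and n_ca >= 5 and n_sh >= 13
    )
    if not default_pseudo_structure and (spec.pseudo_3DS or spec.pseudo_3B):
        raise ValueError("only the study's pseudogene structure (2/6 with mechanisms) is supported")
    f1 = ca_names[4] if default_pseudo_structure else None  # wheat pseudogene family
    fig2 = {}
    if default_pseudo_structure:
        fig2 = {
            sh_names[1]: "TE_INSERTION",
            sh_names[4]: "POINT_FRAMESHIFT",
            sh_names[8]: "INTERNAL_DELETION",
            sh_names[12]: "TERMINAL_TRUNCATION",
        }
    db_pseudo = db_names[1] if default_pseudo_structure and len(db_names) > 1 else None

    # tandem sources: F1 first (its duplicate is itself a pseudogene)
    td_d_sources = []
    if spec.tandem_3DS:
        pool = ([f1] if f1 else []) + [c for c in ca_names if c != f1]
        td_d_sources = pool[: spec.tandem_3DS]
    td_b_sources = [c for c in ca_names if c not in td_d_sources][: spec.tandem_3B]

    shared_pair_families = [
        fam for fam in (ca_names + sh_names)
        if fam != f1 and fam not in fig2 and fam not in td_d_sources and fam not in td_b_sources
    ][: spec.shared_ests_removed]

    two_exon = {name for i, name in enumerate(ca_names) if i % 5 == 1}
    two_exon |= {name for i, name in enumerate(sh_names) if i % 6 == 1}  # includes the TE family

    # --- family sequences ---
    genes: Dict[str, Dict[str, _FamilyGene]] = {WHEAT_D: {}, WHEAT_B: {}, BRACHY: {}, RICE: {}}
    reference_db: List[SequenceRecord] = []

    def new_orf() -> str:
        return random_orf(rng, int(rng.integers(220, 400)))

    for fam in ca_names + crw_names + sh_names:
        kind = "CA" if fam in ca_names else ("CRW" if fam in crw_names else "SH")
        anc = new_orf()
        wheat_anc = mutate(rng, anc, 0.075, preserve_orf=True)
        protect: Set[int] = set()
        if fam in shared_pair_families:
            w0 = int(rng.integers(10, len(wheat_anc) - 150))
            protect = set(range(w0, w0 + 135))
        if fam == f1:
            # premature stop planted before divergence of the wheat genomes
            stop_codon = (len(wheat_anc) // 3) * 2 // 5
            pos = stop_codon * 3
            reference_db.append(SequenceRecord(id=f"REF_{fam}", residues=wheat_anc))
            wheat_anc = wheat_anc[:pos] + "TAA" + wheat_anc[pos + 3:]
        d_cds = mutate(rng, wheat_anc, 0.025, protect=protect, preserve_orf=True)
        b_cds = mutate(rng, wheat_anc, 0.025, protect=protect, preserve_orf=True)
        status = "pseudogene" if fam == f1 else "intact"
        genes[WHEAT_D][fam] = _FamilyGene(fam, kind, d_cds, status=status, two_exon=fam in two_exon)
        genes[WHEAT_B][fam] = _FamilyGene(fam, kind, b_cds, status=status, two_exon=fam in two_exon)
        if kind == "CA":
            genes[BRACHY][fam] = _FamilyGene(fam, kind, mutate(rng, anc, 0.075, preserve_orf=True),
                                             two_exon=fam in two_exon)
        if kind in ("CA", "CRW"):
            genes[RICE][fam] = _FamilyGene(fam, kind, mutate(rng, anc, 0.075, preserve_orf=True),
                                           two_exon=fam in two_exon)

    # tandem duplicates (post-divergence: copied from the locus's own copy)
    for tag, sources in ((WHEAT_D, td_d_sources), (WHEAT_B, td_b_sources)):
        for fam in sources:
            src = genes[tag][fam]
            copy_cds = mutate(rng, src.cds, 0.02, preserve_orf=src.status == "intact")
            genes[tag][f"{fam}.td"] = _FamilyGene(
                f"{fam}.td", "TD", copy_cds, status=src.status, tandem_of=fam,
                two_exon=src.two_exon,
            )

    # the four gene (3DS) - pseudogene (3B) mechanism pairs
    for fam, mech in fig2.items():
        g = genes[WHEAT_B][fam]
        cds = g.cds
        n = len(cds)
        if mech == "TE_INSERTION":
            te = random_dna(rng, 151)
            pos = int(n * 0.85)
            g.cds = cds[:pos] + te + cds[pos:]
            g.te_cds_interval = (pos, pos + 151)
        elif mech == "POINT_FRAMESHIFT":
            pos = n // 2
            g.cds = cds[:pos] + "A" + cds[pos:]
        elif mech == "INTERNAL_DELETION":
            del_len = (int(n * 0.35) // 3) * 3
            start = int(n * 0.30)
            g.cds = cds[:start] + cds[start + del_len:]
        elif mech == "TERMINAL_TRUNCATION":
            keep = min(500, int(n * 0.45))  # a ~500 bp 3' remnant, coverage < 50%
            g.cds = cds[-keep:]
            g.two_exon = False
        g.status = "fragment" if mech == "TERMINAL_TRUNCATION" else "pseudogene"
        g.mechanism = mech

    # locus-specific, excluded and model-genome-only genes
    for tag, names, kind in (
        (WHEAT_D, ds_names, "DS"),
        (WHEAT_B, db_names, "DB"),
        (WHEAT_B, exb_names, "EXB"),
        (BRACHY, bd_names, "BD"),
        (RICE, os_names, "OS"),
    ):
        for fam in names:
            cds = new_orf()
            status = "intact"
            if fam == db_pseudo and kind == "DB":
                reference_db.append(SequenceRecord(id=f"REF_{fam}", residues=cds))
                pos = ((len(cds) // 3) * 2 // 5) * 3
                cds = cds[:pos] + "TAA" + cds[pos + 3:]
                status = "pseudogene"
            if kind == "EXB":
                status = "excluded"
            genes[tag][fam] = _FamilyGene(fam, kind, cds, status=status)

    # --- gene orders ---
    core = _interleave(_insert_evenly(ca_names, crw_names), sh_names)

    def with_tandems(order: List[str], sources: List[str]) -> List[str]:
        out = []
        for fam in order:
            out.append(fam)
            if fam in sources:
                out.append(f"{fam}.td")
        return out

    order_d = _insert_evenly(with_tandems(core, td_d_sources), ds_names)
    order_b = _insert_evenly(with_tandems(core, td_b_sources), db_names + exb_names)
    order_bd = _insert_evenly([f for f in core if f in genes[BRACHY]], bd_names)
    order_os = _insert_evenly([f for f in core if f in genes[RICE]], os_names)

    # --- expression and promoter ground truths (deterministic) ---
    coll_d = ca_names + crw_names
    noncoll_d = sh_names + ds_names + [f"{f}.td" for f in td_d_sources]
    noncoll_b = sh_names + db_names + [f"{f}.td" for f in td_b_sources]

    def pick(candidates: List[str], n: int, forced: Sequence[str] = (), banned: Sequence[str] = ()) -> List[str]:
        out = [c for c in forced if c in candidates]
        for c in candidates:
            if len(out) >= n:
                break
            if c in out or c in banned:
                continue
            out.append(c)
        if len(out) < n:
            raise ValueError("not enough candidates to satisfy the fixture truth counts")
        return out[:n]

    shared_in_ca = [f for f in shared_pair_families if f in ca_names]
    shared_in_sh = [f for f in shared_pair_families if f in sh_names]
    pseudo_b_fams = set(fig2) | ({db_pseudo} if db_pseudo else set()) | ({f1} if f1 else set())
    pseudo_d_fams = ({f1, f"{f1}.td"} if f1 else set())

    expr_d_coll = pick(coll_d, spec.n_expr_3DS_collinear, forced=shared_in_ca, banned=sorted(pseudo_d_fams))
    expr_d_nc = pick(noncoll_d, spec.n_expr_3DS_noncollinear, forced=shared_in_sh, banned=sorted(pseudo_d_fams))
    expr_b_coll = pick(coll_d, spec.n_expr_3B_collinear, banned=shared_in_ca + sorted(pseudo_b_fams))
    expr_b_nc = pick(noncoll_b, spec.n_expr_3B_noncollinear, banned=shared_in_sh + sorted(pseudo_b_fams))

    prom_d_coll = pick(coll_d, spec.n_prom_collinear, banned=sorted(pseudo_d_fams))
    prom_b_coll = pick(coll_d, spec.n_prom_collinear, banned=sorted(pseudo_b_fams))
    prom_d_nc = pick(noncoll_d, spec.n_prom_3DS_noncollinear, banned=sorted(pseudo_d_fams))
    prom_b_nc = pick(noncoll_b, spec.n_prom_3B_noncollinear, banned=sorted(pseudo_b_fams))

    expressed: Dict[str, Set[str]] = {
        WHEAT_D: set(expr_d_coll) | set(expr_d_nc),
        WHEAT_B: set(expr_b_coll) | set(expr_b_nc),
    }
    promoter: Dict[str, Set[str]] = {
        WHEAT_D: set(prom_d_coll) | set(prom_d_nc),
        WHEAT_B: set(prom_b_coll) | set(prom_b_nc),
    }

    # --- locus assembly ---
    loci: List[LocusAnnotation] = []
    orders = {WHEAT_D: order_d, WHEAT_B: order_b, BRACHY: order_bd, RICE: order_os}
    decorative_superfamilies = ("Gypsy", "Copia", "CACTA", "LINE", "Mutator")

    for tag in (WHEAT_D, WHEAT_B, BRACHY, RICE):
        expand = 1.27 if tag == WHEAT_B else 1.0
        parts: List[str] = []
        models: List[GeneModel] = []
        repeats: List[RepeatFeature] = []
        pos = 0
        for k, fam in enumerate(orders[tag]):
            g = genes[tag][fam]
            spacer_len = int(expand * float(rng.integers(1500, 2300)))
            wants_promoter = tag in promoter and fam in promoter[tag]
            spacer = _spacer_with_promoter(rng, spacer_len, wants_promoter, params) \
                if tag in (WHEAT_D, WHEAT_B) else random_dna(rng, spacer_len)
            parts.append(spacer)
            pos += spacer_len
            if k % 4 == 0:  # decorative repeat annotation inside the spacer
                rep_len = int(rng.integers(300, 900))
                rep_start = pos - spacer_len + 100
                repeats.append(
                    RepeatFeature(
                        span=Span(rep_start, rep_start + rep_len),
                        rclass="Retrotransposon" if k % 8 == 0 else "DNA_transposon",
                        order="LTR_retrotransposon" if k % 8 == 0 else "TIR",
                        superfamily=decorative_superfamilies[(k // 4) % len(decorative_superfamilies)],
                        complete=bool(k % 2),
                    )
                )
            start = pos
            if g.two_exon and g.te_cds_interval is None:
                split = (len(g.cds) * 2) // 5
                intron = random_dna(rng, int(rng.integers(90, 150)))
                gene_seq = g.cds[:split] + intron + g.cds[split:]
                exons = [Span(start, start + split),
                         Span(start + split + len(intron), start + len(gene_seq))]
            elif g.te_cds_interval is not None:
                # TE inside the last exon of a two-exon pseudogene
                raw = g.cds
                te0, te1 = g.te_cds_interval
                split = min((len(raw) * 2) // 5, te0 - 30)
                intron = random_dna(rng, int(rng.integers(90, 150)))
                gene_seq = raw[:split] + intron + raw[split:]
                exons = [Span(start, start + split),
                         Span(start + split + len(intron), start + len(gene_seq))]
                repeats.append(
                    RepeatFeature(
                        span=Span(start + split + len(intron) + (te0 - split),
                                  start + split + len(intron) + (te1 - split)),
                        rclass="DNA_transposon",
                        order="TIR",
                        superfamily="CACTA",
                        complete=True,
                    )
                )
            else:
                gene_seq = g.cds
                exons = [Span(start, start + len(gene_seq))]
            parts.append(gene_seq)
            pos += len(gene_seq)
            models.append(
                GeneModel(
                    id=f"{tag}:{fam}",
                    locus_id=tag,
                    strand="+",
                    span=Span(start, pos),
                    exons=exons,
                    status=g.status,
                    notes=[f"family:{fam}"],
                )
            )
        parts.append(random_dna(rng, int(rng.integers(1200, 2000))))
        loci.append(
            LocusAnnotation(
                locus_id=tag,
                genome_tag=tag,
                sequence=SequenceRecord(id=tag, residues="".join(parts)),
                genes=models,
                repeats=repeats,
            )
        )

    fixture_loci = {l.genome_tag: l for l in loci}

    # --- ESTs ---
    expression_truth = {}
    for tag in (WHEAT_D, WHEAT_B):
        for gene in fixture_loci[tag].genes:
            fam = gene.id.split(":", 1)[1]
            if gene.status == "excluded":
                continue
            expression_truth[gene.id] = fam in expressed[tag]
    shared_est_pairs = [
        (f"{WHEAT_D}:{fam}", f"{WHEAT_B}:{fam}") for fam in shared_pair_families
    ]
    ests = generate_ests(
        [fixture_loci[WHEAT_D], fixture_loci[WHEAT_B]],
        expression_truth,
        n_per_expressed=2,
        seed=int(rng.integers(0, 2**31 - 1)),
        params=params,
        shared_pairs=shared_est_pairs,
        n_decoys=2,
    )

    # --- truth tables ---
    rows = []
    for tag in (WHEAT_D, WHEAT_B, BRACHY, RICE):
        for gene in fixture_loci[tag].genes:
            fam = gene.id.split(":", 1)[1]
            g = genes[tag][fam]
            if g.kind in ("CA",):
                category = "COLLINEAR_ALL"
            elif g.kind == "CRW":
                category = "COLLINEAR_RICE_WHEAT"
            elif g.kind == "SH":
                category = "SHARED_WHEAT_NC"
            elif g.kind == "TD":
                category = "TANDEM_DUP_NC"
            elif g.kind == "EXB":
                category = "EXCLUDED"
            else:
                category = "LOCUS_SPECIFIC_NC"
            rows.append(
                {
                    "gene_id": gene.id,
                    "genome": tag,
                    "family": fam,
                    "category": category,
                    "status": g.status,
                    "mechanism": g.mechanism or "",
                    "expressed": expression_truth.get(gene.id, False),
                    "promoter": tag in promoter and fam in promoter.get(tag, set()),
                    "tandem_of": g.tandem_of or "",
                }
            )
    genes_truth = pd.DataFrame(rows)
    pairs_truth = pd.DataFrame(
        [
            {"gene_3DS": f"{WHEAT_D}:{fam}", "gene_3B": f"{WHEAT_B}:{fam}", "family": fam}
            for fam in ca_names + crw_names + sh_names
        ]
    )
    return PaperFixture(
        loci=loci,
        ests=ests,
        reference_db=reference_db,
        genes_truth=genes_truth,
        pairs_truth=pairs_truth,
        shared_est_pairs=shared_est_pairs,
        spec=spec,
    )


def _spacer_with_promoter(
    rng: np.random.Generator,
    length: int,
    wants_promoter: bool,
    params: AnalysisParams,
    max_attempts: int = 60,
) -> str:
    """A spacer whose final ``upstream_len`` bases scan positive (planted
    initiator + TATA box) or negative (rejection-sampled), as requested."""
    for _ in range(max_attempts):
        spacer = list(random_dna(rng, length))
        if wants_promoter:
            d_tss = int(rng.integers(60, 160))          # TSS to ATG distance
            t_off = int(rng.integers(16, 36))           # TATA to TSS distance
            tss_idx = length - d_tss                    # index of the initiator A
            inr = "CTA" + random_dna(rng, 1) + "ATC"    # matches YYANWYY
            spacer[tss_idx - 2:tss_idx + 5] = list(inr)
            spacer[tss_idx - t_off:tss_idx - t_off + 7] = list("TATAAAA")
        candidate = "".join(spacer)
        window = candidate[-params.upstream_len:]
        call = scan_promoter(window, params)
        if call.has_promoter == wants_promoter:
            return candidate
    raise RuntimeError("could not realize the requested promoter truth")
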