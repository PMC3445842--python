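# Methods

This note records the models and procedures implemented in `homeolocus`,
the parameters that matter, and the design choices made where the design
was genuinely open.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Sequence comparison and significance

All homology searches are exact Smith–Waterman local dynamic programming
with affine gaps (Biopython's `PairwiseAligner` as the DP engine), not
heuristic seed-and-extend.  Default scoring: match +2, mismatch −3, gap of
length L costs −5 − 2L.  The match reward follows the analysis being
re-implemented; the penalties are standard nucleotide defaults consistent
with that reward, and all four are configurable (`AnalysisParams`).

Significance uses the ungapped Karlin–Altschul statistic
`E = K·m·n·exp(−λS)` with `(λ, K)` solved numerically for the configured
scoring under uniform base composition: λ from
`Σ p_s·exp(λ·s) = 1` (Brent's method) and K from the lattice-case
renewal-theory series, evaluated by convolving partial-sum distributions
(60 terms).  For +1/−2 this reproduces the published ungapped values
λ = 1.33, K = 0.621 to three figures.  The gapped correction is not
modelled: only the position of the E ≤ 1e-10 cliff matters downstream, and
at the divergence scales analysed (85–95% identity over hundreds of bases)
scores sit orders of magnitude above it.

A shared k-mer prefilter (default k = 13, both strands) skips sequence
pairs before alignment, followed by a score-only DP pass that discards
pairs below the E-value cutoff before the full alignment with statistics is
computed.  Both are skip-only optimizations: at the identity scales of
the analysed and simulated data a significant alignment without a shared
13-mer is vanishingly unlikely, and the property suite compares the
engine against a brute-force reference with the prefilter disabled.

**Pairing.** "Having a homoeolog/ortholog" is operationalized as a
*reciprocal* best hit at E ≤ 1e-10.  Plain best-hit maps are kept alongside
(a tandem-duplicate copy best-matches its source's partner without being
reciprocal) and drive tandem resolution and reference selection.

## Collinearity

The source analysis judges "collinear position" by inspection; here it is
computable: anchors are reciprocal-best pairs between two loci, and a gene
is at a collinear position iff its anchor belongs to the maximum-weight
strictly-increasing chain (longest-increasing-subsequence DP, weights =
alignment identity, ties toward the chain with the earlier query gene).
Chains use gene order only, not strand, so micro-inversions that preserve
order still count as collinear.

Categories: `COLLINEAR_ALL` (in-chain partners in the other wheat locus and
both model genomes), `COLLINEAR_RICE_WHEAT` (in-chain in rice but absent
from Brachypodium), `SHARED_WHEAT_NC` (wheat–wheat pair but no model-genome
in-chain ortholog), `LOCUS_SPECIFIC_NC` (no wheat–wheat pair),
`TANDEM_DUP_NC`, `EXCLUDED` (annotation flag, e.g. a gene in an assembly
gap; excluded genes stay in the homoeolog-percentage denominator but leave
all other fractions).

**Tandem arrays** are runs of nearby same-locus genes (≤ 1 intervening gene
by default) whose best cross-species homolog is the same model-genome gene.
The copy with the highest identity to that ortholog keeps its collinear
eligibility; the others become `TANDEM_DUP_NC` (ties go to the 5'-most
copy; triplet arrays keep a single best copy).  Because tandem copies have
no reciprocal wheat–wheat pair, the per-locus "locus-specific" count
reported in summaries pools `LOCUS_SPECIFIC_NC` and `TANDEM_DUP_NC`; the
same pooling defines the RECENT insertion epoch.

Percentages are reported to one decimal, round-half-up; the homoeolog
fraction as a whole percent.

## Pseudogene calling

A CDS is compared with an intact homolog (a start-to-stop ORF).  Aligned
blocks come from iterated local alignment: because a single optimal local
alignment does not bridge a large internal deletion (two high-scoring
segments outscore one long-gapped path), alignment is repeated with the
previously aligned query interval masked, and high-scoring segments
(score ≥ 45) are chained in coordinate order, tolerating and trimming
≤ 25 bp overlaps at breakpoints.

Defects:

- **Premature stop** — an in-frame stop, read in the homolog-anchored
  frame, before the final 5% of the homolog ORF.  Blocks entered with a
  shifted frame are not scanned (their codon readout is arbitrary).
- **Frameshift** — inter-block indels with net length ≢ 0 (mod 3), required
  to persist ≥ 30 bp before compensation: at 15%+ divergence the optimal
  alignment occasionally inserts a ±1 bp gap pair that a naive rule would
  miscall as two frameshifts.
- **Deletion** — aligned homolog coverage < 70%, i.e. a model missing up to
  30% of its complete homolog still counts as a (deletion-type) pseudogene;
  below 50% coverage with no other defect the model is a *fragment*.  Both
  cutoffs are configurable.

The reference homolog is resolved in order: intact wheat partner → intact
best homolog within the same locus (a tandem copy's natural reference is
its adjacent source) → intact reciprocal model-genome ortholog → best
non-reciprocal model hit → best hit in a user-supplied reference CDS set
(standing in for the public databases the original annotation consulted).
Genes with no intact homolog anywhere are left unassessed.  Within a
homoeologous pair, a deletion-only call against a partner that is itself
shorter is rescinded: the partner carries the deletion, the longer copy's
"missing" sequence is an artifact of an incomplete reference.

**Mechanism attribution** for gene–pseudogene pairs uses regions with 1-kb
flanks and a fixed priority: TE insertion (≥ 50 bp inserted in the
pseudogene, ≤ 10 bp deleted opposite it, overlapping an annotated repeat,
at an exon-aligned position) → single 1–2 bp frameshifting indel → internal
deletion (≥ 30 bp removed, anchored on both sides, ≤ 10 bp inserted) →
terminal truncation (a CDS terminus with no homology in the pseudo region)
→ unknown.  The ≤ 10 bp counter-conditions distinguish true indels from
intron-against-intron gaps, which have unaligned sequence on both sides.

## Insertion epochs and rates

Collinear genes predate the wheat–Brachypodium split (ANCESTRAL; default
35 MYA), wheat-shared non-collinear genes were inserted on the wheat stem
(INTERMEDIATE; the analysis attributes 30 MY to this epoch), and
locus-specific plus tandem-duplicate genes arose after the B/D progenitor
divergence (RECENT; 2.5–4.5 MYA, with the hexaploidization at ~0.5 MYA).
The rate ratio `(n_recent/T) / (n_intermediate/30)` is evaluated at both
ends of the recent-epoch range and reported as an ordered interval; a zero
intermediate count with recent insertions is flagged infinite rather than
raised.  Counts are reported pooled and per locus, since both framings are
in use.

## Expression and promoters

EST support follows the strict rule: only exact matches (100% identity) of
≥ 100 bp between an EST (either strand) and a CDS count, implemented as
k-mer-anchored maximal exact substring detection (verified against a naive
dynamic-programming oracle).  Any EST hitting both members of a
homoeologous pair cannot be assigned to a copy and is removed entirely.  A
gene is "expressed" iff it retains ≥ 1 hit.  Identity thresholds below 100%
are deliberately not implemented for this step.

The promoter scan replaces an external polymerase-II promoter predictor
(whose internal model is unspecified) with a documented heuristic: the TSS
is the best match to the pyrimidine/purine initiator consensus `YYANWYY`
within the final 200 bp of the 1-kb upstream region (ties resolved toward
the start codon; perfect score required by default), and a promoter call
requires a perfect `TATAWAW` box 14–38 bp upstream of the TSS.  A TATA-less
path (initiator score threshold) exists but is disabled by default.
Upstream regions are always reported on the coding strand; regions under
50 bp give a no-call.

The per-pair expression contrast is the exact two-tailed binomial test of
p = 0.5 (summing outcome probabilities ≤ that of the observed count),
delegated to `scipy.stats.binomtest` and verified against closed forms.

## BAC pools and scaffold curation

A minimum-tiling-path clone set is arrayed plate-major/row-major into
384-well plates (rows A–P, columns 1–24; defaults 10 plates).  Plate, row
and column pools place each clone in exactly three pools; deconvolution
intersects the Cartesian product of a marker's positive pools with the
occupied wells (exact for single-clone markers; ambiguity reported
otherwise).  No PCR-error model is applied by default.  Markers hitting
clones in two physical-map contigs contribute overlap edges with
support counts; markers spanning > 2 contigs are flagged.

Scaffold curation aligns end windows (default 1,000 bp, standing in for
full-length terminal reads) against small repetitive contigs, keeping
matches at ≥ 99% identity over ≥ 100 bp that reach a contig terminus
(within 10 bp).  When two different scaffolds match opposite ends of one
contig they are merged — scaffold sequence wins inside overlaps, the
contig's unmatched interior fills the gap — iterating to a fixed point;
a contig matched by more than two scaffold ends is refused and logged.
Ends with a ≥ 100 bp, > 95%-identity hit against a repeat database are
flagged risky and block merging unless independently supported.  Merging
is forward-strand only; reverse-complement orientation resolution is out
of scope.

## Synthetic data

**Simulator.**  Four loci descend from one ancestral gene layout along a
fixed tree: rice and Brachypodium branch at 35 MYA, the wheat B and D
progenitors at a time drawn from 2.5–4.5 MYA (or fixed).  Insertions,
deletions, tandem duplications and pseudogenizations are independent
Poisson processes per lineage; insertion rates are multiplied by an
acceleration factor on the post-split branches.  Default rates follow the
analysed locus's own arithmetic: 0.57 insertions/MY (≈ 17 insertions over
30 MY), acceleration 3, and a 27% B-lineage intergenic expansion.
Substitutions are uniform per site (0.002/site/MY by default, giving ~86%
wheat–model and ~98.5% B–D identity), frame-preserving for intact genes.
Pseudogenization applies one of the four mechanisms literally; every event
is logged with time, lineage and gene, so pipeline output can be compared
with the ground truth exactly.  Intergenic spacers are lineage-independent
random sequence (TE turnover erases intergenic homology on these
timescales) with lognormal lengths (median 17.7 kb by default, matching
the analysed locus's gene spacing); tests and the acceptance harness use
sub-kilobase spacers — gene counts and classifications are unaffected by
spacer length, only sequence volume is.  Simulated genes are single-exon;
intron structure is exercised by the fixture.  The simulator does not
emulate realistic TE sequence models, read-level data, or intergenic
homology, so passing recovery tests demonstrates correctness of the
classification logic, not performance on real assemblies.

**Paper fixture.**  A deterministic generator plants the full printed count
structure (39/38/22/21 genes; 32 pairs; 14 four-way and one rice+wheat
collinear family; 17 shared; 7/5 specific with 3/2 tandems; one excluded
3B gene; 2/6 pseudogenes with the four mechanisms; EST and promoter truths
matching the printed fractions) as concrete sequences: homoeologs at ~95%
identity (2.5% substitutions per copy from a wheat ancestor), orthologs at
~85%, defects applied literally, promoter motifs planted or
rejection-sampled away, ESTs drawn as exact CDS substrings rejection-tested
to match only their source gene, and four shared ESTs drawn from
mutation-protected windows identical in both pair members.  The pipeline —
not the generator's labels — must recover every count, and does so for any
seed; this is what the acceptance harness measures.  Planted identities sit
far from the E-value cliff deliberately; threshold behaviour near the
cliff is exercised separately in unit tests.

## Numerical choices and limitations

- Percentages: round-half-up via `decimal`, one decimal (whole percent for
  the homoeolog fraction).
- Deterministic tie-breaks throughout: best-homolog ties by higher identity
  then lexicographic id; chain ties toward the earlier query gene; tandem
  identity ties toward the 5'-most copy; promoter ties toward the start
  codon.
- All generators are pure functions of (parameters, seed); randomness flows
  from a single `numpy` `SeedSequence`.
- `N` residues are tolerated in locus sequences but rejected inside CDS
  extraction unless explicitly allowed.
- Problem sizes: the bundled fixture uses ~1.5–2.9 kb intergenic spacers
  (~60–130 kb loci) and the recovery suites use 8-gene ancestral layouts
  over 100 replicates; these sizes were chosen so the full suite exercises
  every stage at desk scale.
- Known limitations: no gapped E-value statistics; no splice-aware
  transcript alignment; scaffold merging ignores orientation; the promoter
  scan is a motif heuristic, not a trained promoter model; EST matching
  below 100% identity is not implemented.
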