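"""Anchor chaining, tandem resolution, classification summaries and
locus statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from homeolocus.collinearity import (
    AnchorChain,
    chain_anchors,
    gene_distances,
    repeat_composition,
    round_half_up,
    summarize_collinearity,
)
from homeolocus.model import (
    GeneModel,
    LocusAnnotation,
    RepeatFeature,
    SequenceRecord,
    Span,
)


def exhaustive_best_chain(pairs):
    """Max-weight strictly increasing chain by enumerating all subsets."""
    pairs = sorted(pairs)
    best = 0.0
    for r in range(1, len(pairs) + 1):
        for combo in itertools.combinations(pairs, r):
            if all(a0 < a1 and b0 < b1 for (a0, b0, _), (a1, b1, _) in zip(combo, combo[1:])):
                best = max(best, sum(w for _, _, w in combo))
    return best


class TestChainAnchors:
    def test_already_collinear(self):
        chain = chain_anchors([(1, 1, 1.0), (2, 2, 1.0), (3, 3, 1.0)])
        assert chain.anchors == [(1, 1), (2, 2), (3, 3)]

    def test_crossing_pair_resolved(self):
        # equal weights: one of the two crossing anchors must be dropped
        chain = chain_anchors([(1, 1, 1.0), (2, 3, 1.0), (3, 2, 1.0), (4, 4, 1.0)])
        assert len(chain) == 3
        assert chain.weight == exhaustive_best_chain(
            [(1, 1, 1.0), (2, 3, 1.0), (3, 2, 1.0), (4, 4, 1.0)]
        )

    def test_single_pair(self):
        assert chain_anchors([(5, 9, 2.0)]).anchors == [(5, 9)]

    def test_empty(self):
        assert len(chain_anchors([])) == 0

    def test_duplicate_gene_rejected(self):
        with pytest.raises(ValueError):
            chain_anchors([(1, 1, 1.0), (1, 2, 1.0)])

    @given(
        st.lists(
            st.tuples(st.integers(0, 15), st.integers(0, 15), st.floats(0.5, 5.0)),
            min_size=1, max_size=8,
        )
    )
    def test_matches_exhaustive_search(self, raw):
        seen_a, seen_b, pairs = set(), set(), []
        for a, b, w in raw:  # enforce the one-anchor-per-gene precondition
            if a in seen_a or b in seen_b:
                continue
            seen_a.add(a)
            seen_b.add(b)
            pairs.append((a, b, round(w, 3)))
        if not pairs:
            return
        chain = chain_anchors(pairs)
        assert chain.weight == pytest.approx(exhaustive_best_chain(pairs))
        assert all(a0 < a1 and b0 < b1 for (a0, b0), (a1, b1) in zip(chain.anchors, chain.anchors[1:]))

    def test_reversed_order_yields_singleton(self):
        # anti-collinearity control: reversing one locus leaves chains of length 1
        pairs = [(i, 10 - i, 1.0) for i in range(1, 10)]
        assert len(chain_anchors(pairs)) == 1

    def test_strictly_increasing_invariant_enforced(self):
        with pytest.raises(ValueError):
            AnchorChain(anchors=[(1, 2), (2, 2)], weight=2.0)


class TestResolveTandem:
    def test_fixture_tandem_counts(self, paper_result):
        s = paper_result.summary.set_index("genome")
        assert s.loc["3DS", "n_tandem"] == 3
        assert s.loc["3B", "n_tandem"] == 2

    def test_tandem_partner_is_collinear_source(self, paper_result, paper_fixture):
        truth = paper_fixture.genes_truth.set_index("gene_id")
        for prof in paper_result.profiles:
            if prof.category == "TANDEM_DUP_NC":
                src_fam = truth.loc[prof.gene_id, "tandem_of"]
                assert prof.tandem_partner == f"{prof.genome_tag}:{src_fam}"

    def test_adjacent_genes_with_different_homologs_untouched(self, paper_result):
        # every non-tandem gene keeps its chain-derived category
        cats = {p.gene_id: p.category for p in paper_result.profiles}
        assert cats["3DS:CA01"] == "COLLINEAR_ALL"
        assert cats["3DS:SH01"] == "SHARED_WHEAT_NC"


class TestSummaries:
    def test_empty_profiles_give_empty_table(self):
        table = summarize_collinearity([])
        assert len(table) == 0

    def test_rounding_half_up(self):
        assert round_half_up(63.65, 1) == 63.7
        assert round_half_up(84.21, 0) == 84.0
        assert round_half_up(38.46, 1) == 38.5


class TestGeneDistances:
    def _locus(self, spans):
        genes = [
            GeneModel(id=f"g{i}", locus_id="L", strand="+", span=Span(*s), exons=[Span(*s)])
            for i, s in enumerate(spans)
        ]
        return LocusAnnotation(
            locus_id="L", genome_tag="t",
            sequence=SequenceRecord(id="L", residues="A" * 2000), genes=genes,
        )

    def test_hand_case(self):
        mean, median, dists = gene_distances(self._locus([(0, 100), (300, 400), (900, 1000)]))
        assert dists == [200, 500]
        assert mean == 350 and median == 350

    def test_two_genes(self):
        mean, median, dists = gene_distances(self._locus([(0, 100), (250, 400)]))
        assert dists == [150] and mean == median == 150

    def test_single_gene_rejected(self):
        with pytest.raises(ValueError):
            gene_distances(self._locus([(0, 100)]))


class TestRepeatComposition:
    def test_printed_superfamily_shares(self):
        # cumulative lengths as printed in the repeat-composition table:
        # Gypsy 354,331 of 1,059,398 total -> 33.4%
        lengths = {
            "Copia": 236_440, "Gypsy": 354_331, "LINE": 16_607, "CACTA": 256_633,
            "Harbinger": 433, "Mutator": 3_609, "Mariner": 5_096, "unclassified": 128_095,
        }
        # pad unclassified so the total matches the printed 1,059,398
        total = sum(lengths.values())
        lengths["unclassified"] += 1_059_398 - total
        repeats = []
        for fam, length in lengths.items():
            repeats.append(RepeatFeature(span=Span(0, length), rclass="any", order="any",
                                         superfamily=fam))
        table = repeat_composition(repeats).set_index("superfamily")
        assert table.loc["Gypsy", "pct_of_repeats"] == 33.4
        assert table.loc["Copia", "pct_of_repeats"] == 22.3
        assert table.loc["CACTA", "pct_of_repeats"] == 24.2

    def test_single_repeat_is_total(self):
        table = repeat_composition(
            [RepeatFeature(span=Span(0, 100), rclass="c", order="o", superfamily="Gypsy")]
        )
        assert table.pct_of_repeats.tolist() == [100.0]

    def test_equal_split(self):
        table = repeat_composition(
            [
                RepeatFeature(span=Span(0, 100), rclass="c", order="o", superfamily="Gypsy"),
                RepeatFeature(span=Span(200, 300), rclass="c", order="o", superfamily="Copia"),
            ]
        )
        assert sorted(table.pct_of_repeats) == [50.0, 50.0]


class TestCategoryPartition:
    def test_categories_partition_fixture_loci(self, paper_result):
        counts = {}
        for p in paper_result.profiles:
            counts[p.genome_tag] = counts.get(p.genome_tag, 0) + 1
        assert counts["3DS"] == 39 and counts["3B"] == 38
        assert counts["Bd2"] == 22 and counts["Os1"] == 21
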