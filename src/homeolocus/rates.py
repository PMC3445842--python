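"""Insertion-epoch assignment and insertion-rate-ratio arithmetic.

Collinearity categories map onto insertion epochs: collinear genes predate
the wheat-Brachypodium split (ANCESTRAL), wheat-shared non-collinear genes
were inserted between that split and the divergence of the wheat B and D
progenitors (INTERMEDIATE), and locus-specific or tandem-duplicated copies
arose afterwards (RECENT).  The rate ratio compares the recent per-MY
insertion rate against the intermediate epoch's, evaluated at both ends of
the (uncertain) B/D divergence-time range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

from .params import AnalysisParams, DEFAULT_PARAMS

EPOCHS = ("ANCESTRAL", "INTERMEDIATE", "RECENT")

_CATEGORY_EPOCH = {
    "COLLINEAR_ALL": "ANCESTRAL",
    "COLLINEAR_RICE_WHEAT": "ANCESTRAL",
    "SHARED_WHEAT_NC": "INTERMEDIATE",
    "LOCUS_SPECIFIC_NC": "RECENT",
    "TANDEM_DUP_NC": "RECENT",
}


@dataclass
class EpochAssignment:
    gene_id: str
    genome_tag: str
    epoch: str


@dataclass
class RateEstimate:
    epoch: str
    count: int
    duration: Tuple[float, float]  # MY range (point ranges allowed)
    rate: Tuple[float, float]      # events/MY at the range endpoints


@dataclass
class RateRatio:
    low: float
    high: float
    infinite: bool = False


def assign_epochs(profiles: Sequence, params: AnalysisParams = DEFAULT_PARAMS) -> List[EpochAssignment]:
    """Map classified profiles to insertion epochs; EXCLUDED genes are skipped."""
    out = []
    for prof in profiles:
        if prof.category == "EXCLUDED":
            continue
        epoch = _CATEGORY_EPOCH.get(prof.category)
        if epoch is None:
            raise ValueError(f"gene {prof.gene_id}: unclassified category {prof.category!r}")
        out.append(EpochAssignment(gene_id=prof.gene_id, genome_tag=prof.genome_tag, epoch=epoch))
    return out


def insertion_rate_ratio(
    n_intermediate: int,
    n_recent: int,
    t_old: float,
    t_recent_range: Tuple[float, float],
) -> RateRatio:
    """(recent rate) / (intermediate rate) at both endpoints of the recent span.

    Returned ordered with the low ratio at the larger recent duration.  A
    zero intermediate count with recent insertions flags an infinite ratio
    rather than raising.
    """
    if n_intermediate < 0 or n_recent < 0:
        raise ValueError("counts must be non-negative")
    t_lo, t_hi = t_recent_range
    if t_old <= 0 or t_lo <= 0 or t_hi <= 0:
        raise ValueError("durations must be positive")
    if n_intermediate == 0:
        if n_recent == 0:
            return RateRatio(low=0.0, high=0.0)
        return RateRatio(low=float("inf"), high=float("inf"), infinite=True)
    rate_old = n_intermediate / t_old
    low = (n_recent / max(t_lo, t_hi)) / rate_old
    high = (n_recent / min(t_lo, t_hi)) / rate_old
    return RateRatio(low=low, high=high)
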