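"""Three-dimensional BAC pool design, marker deconvolution and physical-map
contig-overlap inference.

A minimum-tiling-path clone set is arrayed into 384-well plates (rows A-P,
columns 1-24); plate, row and column pools place every clone in exactly
three pools.  A PCR marker's positive pools are deconvoluted back to clone
addresses by intersecting the Cartesian product of positive pools with the
occupied wells.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

Address = Tuple[int, str, int]  # (plate number, row letter, column number)

ROW_LETTERS = string.ascii_uppercase


@dataclass
class PoolDesign:
    n_plates: int
    n_rows: int
    n_cols: int
    clone_to_address: Dict[str, Address]
    address_to_clone: Dict[Address, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.address_to_clone:
            self.address_to_clone = {a: c for c, a in self.clone_to_address.items()}

    @property
    def n_pools(self) -> int:
        return self.n_plates + self.n_rows + self.n_cols

    def pools_of(self, clone: str) -> Tuple[str, str, str]:
        plate, row, col = self.clone_to_address[clone]
        return (f"plate:{plate}", f"row:{row}", f"col:{col}")

    def positive_pools(self, clones: Sequence[str]) -> "ScreenResult":
        plates, rows, cols = set(), set(), set()
        for clone in clones:
            plate, row, col = self.clone_to_address[clone]
            plates.add(plate)
            rows.add(row)
            cols.add(col)
        return ScreenResult(
            marker_id="",
            plates=sorted(plates),
            rows=sorted(rows),
            cols=sorted(cols),
        )


@dataclass
class ScreenResult:
    marker_id: str
    plates: List[int]
    rows: List[str]
    cols: List[int]


@dataclass
class Deconvolution:
    marker_id: str
    candidates: List[str]          # clone names, sorted
    ambiguity: int
    no_call: bool = False


def design_pools(
    clone_list: Sequence[str],
    n_plates: int = 10,
    n_rows: int = 16,
    n_cols: int = 24,
) -> PoolDesign:
    """Fill wells plate-major, row-major, column-minor (deterministic)."""
    capacity = n_plates * n_rows * n_cols
    if len(clone_list) > capacity:
        raise ValueError(f"{len(clone_list)} clones exceed pool capacity {capacity}")
    if len(set(clone_list)) != len(clone_list):
        raise ValueError("clone names must be unique")
    addresses = (
        (plate, ROW_LETTERS[row], col + 1)
        for plate in range(1, n_plates + 1)
        for row in range(n_rows)
        for col in range(n_cols)
    )
    mapping = dict(zip(clone_list, addresses))
    return PoolDesign(n_plates=n_plates, n_rows=n_rows, n_cols=n_cols, clone_to_address=mapping)


def deconvolve(design: PoolDesign, screen: ScreenResult) -> Deconvolution:
    """Candidate clones = Cartesian product of positive pools, intersected
    with occupied wells.  An empty dimension yields a no-call."""
    if not screen.plates or not screen.rows or not screen.cols:
        return Deconvolution(marker_id=screen.marker_id, candidates=[], ambiguity=0, no_call=True)
    candidates = []
    for plate, row, col in itertools.product(screen.plates, screen.rows, screen.cols):
        clone = design.address_to_clone.get((plate, row, col))
        if clone is not None:
            candidates.append(clone)
    candidates.sort()
    return Deconvolution(
        marker_id=screen.marker_id,
        candidates=candidates,
        ambiguity=len(candidates),
    )


@dataclass
class ContigOverlap:
    contig_a: str
    contig_b: str
    support: int
    markers: List[str]


def infer_contig_overlaps(
    marker_to_clones: Dict[str, Sequence[str]],
    clone_to_contig: Dict[str, str],
) -> Tuple[List[ContigOverlap], List[str]]:
    """Overlap edges between physical-map contigs from multi-contig markers.

    Each marker hitting clones in two (or more) contigs contributes one
    supporting observation per contig pair; markers spanning more than two
    contigs are additionally flagged as unusual.
    """
    edges: Dict[Tuple[str, str], List[str]] = {}
    flagged: List[str] = []
    for marker, clones in sorted(marker_to_clones.items()):
        contigs = set()
        for clone in clones:
            if clone not in clone_to_contig:
                raise ValueError(f"clone {clone!r} has no contig assignment")
            contigs.add(clone_to_contig[clone])
        if len(contigs) > 2:
            flagged.append(marker)
        for a, b in itertools.combinations(sorted(contigs), 2):
            edges.setdefault((a, b), []).append(marker)
    out = [
        ContigOverlap(contig_a=a, contig_b=b, support=len(markers), markers=markers)
        for (a, b), markers in sorted(edges.items())
    ]
    return out, flagged
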