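"""Random-sequence primitives for the generators: ORF construction and
divergence with a uniform (Jukes-Cantor-like) substitution process.

Only identity thresholds matter downstream, so substitutions are uniform
across sites; mutation of intact coding sequences preserves the reading
frame (start codon, terminal stop, no new in-frame stops).
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence, Set

import numpy as np

BASES = "ACGT"
STOP_CODONS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = [
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in STOP_CODONS
]


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def random_orf(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n_codons - 2) random non-stop codons + stop codon."""
    if n_codons < 3:
        raise ValueError("ORF needs at least 3 codons")
    body = rng.integers(0, len(_NONSTOP_CODONS), size=n_codons - 2)
    stop = rng.choice(sorted(STOP_CODONS))
    return "ATG" + "".join(_NONSTOP_CODONS[i] for i in body) + stop


def mutate(
    rng: np.random.Generator,
    seq: str,
    rate: float,
    protect: Optional[Set[int]] = None,
    preserve_orf: bool = False,
) -> str:
    """Substitute a ``rate`` fraction of sites uniformly at random.

    ``protect`` positions are never touched.  With ``preserve_orf`` the
    start codon and terminal stop are protected and substitutions that
    would create a new in-frame stop codon (or destroy/alter an existing
    in-frame stop) are redrawn at another site, so intact genes stay intact
    and planted defects stay planted.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    protect = set(protect or ())
    chars = list(seq)
    n = len(chars)
    if preserve_orf:
        protect |= {0, 1, 2, n - 3, n - 2, n - 1}
        # existing in-frame stops (planted defects) are left untouched
        for i in range(0, n - 2, 3):
            if seq[i:i + 3] in STOP_CODONS:
                protect |= {i, i + 1, i + 2}
    n_mut = int(round(rate * n))
    eligible = [i for i in range(n) if i not in protect]
    if n_mut == 0 or not eligible:
        return seq
    eligible = [eligible[i] for i in rng.permutation(len(eligible))]
    done = 0
    for pos in eligible:
        if done >= n_mut:
            break
        old = chars[pos]
        choices = [b for b in BASES if b != old]
        new = choices[rng.integers(0, 3)]
        if preserve_orf:
            codon_start = (pos // 3) * 3
            trial = chars[codon_start:codon_start + 3]
            trial[pos - codon_start] = new
            if "".join(trial) in STOP_CODONS:
                continue  # redraw at another site
        chars[pos] = new
        done += 1
    return "".join(chars)


def expected_identity(*rates: float) -> float:
    """Expected percent identity after independent divergence at the given
    per-copy substitution fractions (ignoring back-mutations)."""
    p = 1.0
    for r in rates:
        p *= 1.0 - r
    return 100.0 * p
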