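"""Analysis parameters shared by every pipeline stage.

All thresholds come with the defaults used throughout the comparative
analysis: an E-value cutoff of 1e-10 for homology searches, a nucleotide
match reward of +2, the 100%-identity / 100-bp rule for EST support, the
99% / 100-bp rule for scaffold-end merging, the 95% / 100-bp rule for
repeat screening of scaffold ends, the 30%-of-homolog deletion threshold
for pseudogene calls, 1-kb upstream promoter windows, a 14-38-bp
TATA-to-TSS window, and the divergence times (in million years, MY) used
for insertion-epoch arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Tuple

import yaml


@dataclass
class AnalysisParams:
    # homology search
    evalue_max: float = 1e-10
    match_reward: int = 2
    mismatch_penalty: int = -3
    gap_open: int = -5          # cost of a gap of length L: gap_open + L * gap_extend
    gap_extend: int = -2
    prefilter_k: int = 13       # shared k-mer prefilter; skip-only optimization

    # EST expression scoring
    est_min_len: int = 100
    est_min_identity: float = 100.0

    # scaffold curation
    merge_min_identity: float = 99.0
    merge_min_len: int = 100
    repeat_screen_min_identity: float = 95.0
    repeat_screen_min_len: int = 100
    end_window: int = 1000

    # pseudogene assessment
    pseudo_deletion_frac: float = 0.30   # missing up to this fraction => deletion defect
    fragment_coverage: float = 0.50      # below this coverage => fragment
    premature_stop_tail_frac: float = 0.05
    frameshift_min_extent: int = 30      # bp an out-of-frame stretch must persist
    min_internal_deletion: int = 30      # bp, mechanism attribution
    min_te_insertion: int = 50           # bp, mechanism attribution

    # promoter scan
    upstream_len: int = 1000
    tata_tss_range: Tuple[int, int] = (14, 38)
    tss_search_window: int = 200
    min_inr_score: int = 7               # perfect YYANWYY
    tata_less_min_score: int | None = None  # None disables the TATA-less path

    # collinearity / tandem resolution
    tandem_max_intervening: int = 1

    # divergence times (MY)
    t_brachy_split: float = 35.0
    t_barley_split: float = 10.0
    t_bd_split_range: Tuple[float, float] = (2.5, 4.5)
    t_tetraploid: float = 0.5
    t_old: float = 30.0                  # span of the pre-divergence insertion epoch

    def __post_init__(self) -> None:
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be positive")
        if self.match_reward <= 0:
            raise ValueError("match_reward must be positive")
        if self.mismatch_penalty >= 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("penalties must be negative")
        for name in ("est_min_identity", "merge_min_identity", "repeat_screen_min_identity"):
            v = getattr(self, name)
            if not 0 < v <= 100:
                raise ValueError(f"{name} must be in (0, 100]")
        for name in ("est_min_len", "merge_min_len", "repeat_screen_min_len", "upstream_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.tata_tss_range
        if not 0 < lo < hi:
            raise ValueError("tata_tss_range must be an ordered positive pair")
        lo, hi = self.t_bd_split_range
        if not 0 < lo <= hi:
            raise ValueError("t_bd_split_range must be ordered")
        if not 0 <= self.pseudo_deletion_frac < 1:
            raise ValueError("pseudo_deletion_frac must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("tata_tss_range", "t_bd_split_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["tata_tss_range"] = list(self.tata_tss_range)
        data["t_bd_split_range"] = list(self.t_bd_split_range)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


DEFAULT_PARAMS = AnalysisParams()
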