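"""Pipeline parameters and their defaults."""

from __future__ import annotations

from dataclasses import dataclass, field, fields


@dataclass
class Params:
    """Tuning knobs shared by the whole correction pipeline.

    Defaults follow the reference configuration: 500-base windows
    overlapping by 50, a minimum per-base support of 3 reads, at most 150
    overlaps kept per pile, 9-mers for both anchor chaining and polishing,
    a k-mer solidity threshold of 4, an anchor-pair support threshold of 8
    and at least 2 chain anchors required to process a window.
    """

    window_length: int = 500          # L
    window_overlap: int = 50          # O
    min_support: int = 3              # C
    max_overlaps: int = 150           # N
    k: int = 9
    kmer_solidity: int = 4            # minimum k-mer frequency to be solid
    anchor_support: int = 8           # T, sequences backing an anchor pair
    min_anchors: int = 2
    flank_solid: int = 3              # n solid k-mers flanking a weak region
    segmentation: bool = True         # anchor-chain segmentation on/off
    match_score: int = 2
    mismatch_score: int = -3
    gap_score: int = -2               # linear gap
    realign_min_identity: float = 0.5
    dbg_max_expansions: int = 1000    # backtracking budget per anchor pair
    chain_max_expansions: int = 4000

    def __post_init__(self) -> None:
        if not 0 <= self.window_overlap < self.window_length:
            raise ValueError("require 0 <= window_overlap < window_length")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if self.max_overlaps < 1:
            raise ValueError("max_overlaps must be >= 1")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.min_anchors < 2:
            raise ValueError("min_anchors must be >= 2")
        if self.mismatch_score >= 0 or self.gap_score >= 0:
            raise ValueError("mismatch/gap scores must be negative")

    def replace(self, **kwargs) -> "Params":
        values = {f.name: getattr(self, f.name) for f in fields(self)}
        values.update(kwargs)
        return Params(**values)
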