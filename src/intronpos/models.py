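"""Domain containers shared across the pipeline.

All coordinates are 1-based inclusive genomic intervals (the GFF3/GTF
convention).  Intron indices are counted in transcription (5'->3')
direction, so index 1 is always the 5'-most intron regardless of strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

import pandas as pd

THIRD_BINS = ("first", "second", "third")
ABSOLUTE_GROUPS = ("I1", "I2", "I3", "I4", "I5", ">I5")
RELATIVE_GROUPS = ("first", "second", "third", "middle", "last")
CATEGORIES = ABSOLUTE_GROUPS + THIRD_BINS


@dataclass
class GeneModel:
    """One gene's selected-transcript exon/intron structure.

    ``exons`` are stored in genomic coordinate order; ``intron_lengths``
    in transcription order (reversed relative to genomic order on the
    minus strand).  ``exons`` may be empty when the model was read from
    a plain length table.
    """

    gene_id: str
    symbol: str
    transcript_id: Optional[str]
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    intron_lengths: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if any(l < 1 for l in self.intron_lengths):
            raise ValueError(f"gene {self.gene_id}: intron length < 1")
        if self.exons and len(self.exons) - 1 != len(self.intron_lengths):
            raise ValueError(
                f"gene {self.gene_id}: {len(self.exons)} exons inconsistent "
                f"with {len(self.intron_lengths)} introns"
            )

    @property
    def n_introns(self) -> int:
        return len(self.intron_lengths)


@dataclass(frozen=True)
class LongestIntronRecord:
    """Per-gene longest-intron position summary.

    ``i`` is the 1-based transcription-direction index of the longest
    intron (5'-most index on ties), ``N`` the intron count, ``L`` the
    longest length in bp and ``r`` the exact rational relative position
    i/N.  ``third_bin`` partitions r into (0,1/3], (1/3,2/3], (2/3,1];
    ``is_middle`` (r == 1/2) and ``is_last`` (i == N) are overlapping
    flags on top of the thirds.
    """

    gene_id: str
    N: int
    i: int
    L: int
    tie: bool
    r: Fraction
    third_bin: str
    is_middle: bool
    is_last: bool


@dataclass
class PositionDistribution:
    """Counts and percentages of longest-intron positions in a collection."""

    n_genes: int
    min_introns: int
    absolute_counts: dict[str, int]          # I1..I5 and ">I5"
    absolute_pct: dict[str, float]
    index_histogram: dict[int, int]          # full per-index counts
    relative_counts: dict[str, int]          # three third-bins
    relative_pct: dict[str, float]
    middle_count: int
    middle_pct: float
    last_count: int
    last_pct: float


@dataclass
class LengthByPosition:
    """Longest-intron length medians per position group with pairwise tests."""

    grouping: str                            # "absolute" | "relative"
    groups: tuple[str, ...]
    n: dict[str, int]
    median: dict[str, float]
    p_raw: dict[tuple[str, str], float]      # two-sided Mann-Whitney
    p_bonferroni: dict[tuple[str, str], float]
    insufficient: set[tuple[str, str]]


@dataclass
class CountSummary:
    """Collection-level intron-count summary."""

    n_genes: int
    intronless_pct: float
    mean: float
    median: float
    max: int
    argmax_gene_id: str
    modal_counts: list[tuple[int, int]]      # (count, frequency), most frequent first
    shapiro_stat: float
    shapiro_p: float


@dataclass
class SetComparison:
    """One 2x2 Fisher comparison of a query set against a reference.

    ``table`` rows are {query, reference}, columns {in category, not in
    category}.  ``odds_ratio`` is None when b*c == 0.
    """

    category: str
    table: tuple[tuple[int, int], tuple[int, int]]
    query_pct: float
    reference_pct: float
    odds_ratio: Optional[float]
    p: float
    p_bonferroni: float
    zero_margin: bool = False


class ExpressionTable:
    """Gene x tissue nTPM matrix (genes indexed by symbol)."""

    def __init__(self, values: pd.DataFrame):
        if (values.to_numpy() < 0).any():
            raise ValueError("nTPM values must be non-negative")
        self.values = values

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class TissueStrataResult:
    """Per-tissue expression comparison across position groups."""

    tissue: str
    grouping: str
    group_n: dict[str, int]
    group_median: dict[str, float]
    kw_p: float
    p_raw: dict[tuple[str, str], float]
    p_bonferroni: dict[tuple[str, str], float]
    direction: dict[tuple[str, str], int]    # sign of median(g1) - median(g2)
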