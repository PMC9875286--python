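"""Longest-intron position statistics over a gene collection.

Per gene the longest intron's absolute index i (transcription
direction, 5'-most on ties) and its exact rational relative position
r = i/N are computed; collection-level summaries cover the absolute-
and relative-position frequency distributions, length medians per
position group with pairwise rank tests, and the intron-count summary.

Positional statistics deliberately use exact integer arithmetic for the
third-bin boundaries: r <= 1/3 is decided by 3*i <= N, never by
floating-point division, so boundary genes (e.g. i=1, N=3) land in the
first third deterministically.
"""

from __future__ import annotations

import logging
from collections import Counter
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .models import (
    ABSOLUTE_GROUPS,
    CATEGORIES,
    RELATIVE_GROUPS,
    THIRD_BINS,
    CountSummary,
    GeneModel,
    LengthByPosition,
    LongestIntronRecord,
    PositionDistribution,
)

logger = logging.getLogger(__name__)

RECORD_HEADER = "gene_id\tN\ti\tL\ttie\tr_num\tr_den\tthird_bin\tis_middle\tis_last"


class IntronlessGene(ValueError):
    """Raised when a positional statistic is requested for a gene with no introns."""


def categorize_relative(i: int, N: int) -> tuple[str, bool, bool]:
    """Classify relative position i/N into a third bin plus middle/last flags.

    Bins are (0,1/3] -> "first", (1/3,2/3] -> "second", (2/3,1] ->
    "third"; decided as 3*i vs N and 2*N in integers.  ``is_middle`` is
    2*i == N (even N only); ``is_last`` is i == N.
    """
    if not 1 <= i <= N:
        raise ValueError(f"index i={i} out of range for N={N}")
    if 3 * i <= N:
        third_bin = "first"
    elif 3 * i <= 2 * N:
        third_bin = "second"
    else:
        third_bin = "third"
    return third_bin, 2 * i == N, i == N


def longest_intron(gene: GeneModel) -> LongestIntronRecord:
    """Locate the longest intron of one gene and derive its position record."""
    N = gene.n_introns
    if N == 0:
        raise IntronlessGene(f"gene {gene.gene_id} has no introns")
    lengths = gene.intron_lengths
    L = max(lengths)
    i = lengths.index(L) + 1  # 5'-most index attaining the maximum
    tie = lengths.count(L) > 1
    third_bin, is_middle, is_last = categorize_relative(i, N)
    return LongestIntronRecord(
        gene_id=gene.gene_id,
        N=N,
        i=i,
        L=L,
        tie=tie,
        r=Fraction(i, N),
        third_bin=third_bin,
        is_middle=is_middle,
        is_last=is_last,
    )


def records_from_genes(genes: Iterable[GeneModel]) -> list[LongestIntronRecord]:
    """Longest-intron records for every intron-bearing gene (intronless skipped)."""
    out = []
    n_intronless = 0
    for g in genes:
        if g.n_introns == 0:
            n_intronless += 1
            continue
        out.append(longest_intron(g))
    if n_intronless:
        logger.info("records_from_genes: %d intronless gene(s) excluded", n_intronless)
    return out


def record_in_category(rec: LongestIntronRecord, category: str) -> bool:
    """Membership of a record in an absolute (I1..I5, >I5) or third-bin category."""
    if category == ">I5":
        return rec.i > 5
    if category.startswith("I"):
        return rec.i == int(category[1:])
    if category in THIRD_BINS:
        return rec.third_bin == category
    if category == "middle":
        return rec.is_middle
    if category == "last":
        return rec.is_last
    raise ValueError(f"unknown category {category!r}")


def filter_records(
    records: Sequence[LongestIntronRecord], min_introns: int
) -> list[LongestIntronRecord]:
    return [r for r in records if r.N >= min_introns]


def position_distribution(
    records: Sequence[LongestIntronRecord], min_introns: int = 3
) -> PositionDistribution:
    """Absolute and relative longest-intron position frequencies.

    Genes with fewer than ``min_introns`` introns are excluded first (so
    small-N genes do not distort the relative bins); ">I5" pools every
    absolute index above 5.  Percentages are over the filtered count.
    """
    kept = filter_records(records, min_introns)
    if not kept:
        raise ValueError("no records left after min_introns filter")
    n = len(kept)
    hist = Counter(r.i for r in kept)
    abs_counts = {
        f"I{k}": hist.get(k, 0) for k in range(1, 6)
    }
    abs_counts[">I5"] = sum(c for idx, c in hist.items() if idx > 5)
    rel_counts = Counter(r.third_bin for r in kept)
    middle = sum(r.is_middle for r in kept)
    last = sum(r.is_last for r in kept)
    pct = lambda c: 100.0 * c / n
    return PositionDistribution(
        n_genes=n,
        min_introns=min_introns,
        absolute_counts=abs_counts,
        absolute_pct={k: pct(v) for k, v in abs_counts.items()},
        index_histogram=dict(sorted(hist.items())),
        relative_counts={b: rel_counts.get(b, 0) for b in THIRD_BINS},
        relative_pct={b: pct(rel_counts.get(b, 0)) for b in THIRD_BINS},
        middle_count=middle,
        middle_pct=pct(middle),
        last_count=last,
        last_pct=pct(last),
    )


def mann_whitney_two_sided(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value (exact for small tie-free samples)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0  # degenerate: no variation at all
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method="auto").pvalue)


def group_records(
    records: Sequence[LongestIntronRecord], grouping: str
) -> dict[str, list[LongestIntronRecord]]:
    """Partition (absolute) or cover (relative; middle/last overlap thirds)."""
    if grouping == "absolute":
        groups = ABSOLUTE_GROUPS
    elif grouping == "relative":
        groups = RELATIVE_GROUPS
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    return {g: [r for r in records if record_in_category(r, g)] for g in groups}


def length_by_position(
    records: Sequence[LongestIntronRecord],
    grouping: str = "absolute",
    min_introns: int = 3,
) -> LengthByPosition:
    """Longest-intron length medians per position group with pairwise tests.

    Absolute grouping uses I1..I5 and ">I5"; relative grouping uses the
    three thirds plus the overlapping "middle" and "last" flags.  All
    pairwise two-sided Mann-Whitney p-values are reported raw and
    Bonferroni-adjusted; pairs with a group below two members are
    flagged insufficient.
    """
    kept = filter_records(records, min_introns)
    by_group = group_records(kept, grouping)
    groups = tuple(by_group)
    n = {g: len(v) for g, v in by_group.items()}
    median = {
        g: float(np.median([r.L for r in v])) if v else float("nan")
        for g, v in by_group.items()
    }
    pairs = [
        (g1, g2) for a, g1 in enumerate(groups) for g2 in groups[a + 1:]
    ]
    p_raw: dict[tuple[str, str], float] = {}
    insufficient: set[tuple[str, str]] = set()
    for g1, g2 in pairs:
        if n[g1] < 2 or n[g2] < 2:
            insufficient.add((g1, g2))
            p_raw[(g1, g2)] = float("nan")
            continue
        p_raw[(g1, g2)] = mann_whitney_two_sided(
            [r.L for r in by_group[g1]], [r.L for r in by_group[g2]]
        )
    m = len(pairs) - len(insufficient)
    p_bonf = {
        pair: min(1.0, p * m) if pair not in insufficient else float("nan")
        for pair, p in p_raw.items()
    }
    return LengthByPosition(
        grouping=grouping,
        groups=groups,
        n=n,
        median=median,
        p_raw=p_raw,
        p_bonferroni=p_bonf,
        insufficient=insufficient,
    )


def count_summary(genes: Sequence[GeneModel]) -> CountSummary:
    """Intron-count distribution summary with a Shapiro-Wilk normality check."""
    if not genes:
        raise ValueError("empty gene collection")
    counts = np.array([g.n_introns for g in genes])
    argmax_gene = max(genes, key=lambda g: (g.n_introns, g.gene_id)).gene_id
    freq = Counter(counts.tolist())
    modal = sorted(freq.items(), key=lambda kv: (-kv[1], kv[0]))[:5]
    if len(counts) >= 3 and np.ptp(counts) > 0:
        sw = stats.shapiro(counts)
        sw_stat, sw_p = float(sw.statistic), float(sw.pvalue)
    else:
        sw_stat, sw_p = float("nan"), float("nan")
    return CountSummary(
        n_genes=len(genes),
        intronless_pct=100.0 * float(np.mean(counts == 0)),
        mean=float(counts.mean()),
        median=float(np.median(counts)),
        max=int(counts.max()),
        argmax_gene_id=argmax_gene,
        modal_counts=modal,
        shapiro_stat=sw_stat,
        shapiro_p=sw_p,
    )


def write_records(records: Iterable[LongestIntronRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(RECORD_HEADER + "\n")
        for r in records:
            fh.write(
                f"{r.gene_id}\t{r.N}\t{r.i}\t{r.L}\t{int(r.tie)}\t"
                f"{r.r.numerator}\t{r.r.denominator}\t{r.third_bin}\t"
                f"{int(r.is_middle)}\t{int(r.is_last)}\n"
            )


def read_records(path: str | Path) -> list[LongestIntronRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header != RECORD_HEADER:
            raise ValueError(f"{path}: unexpected record header")
        for line in fh:
            gene_id, N, i, L, tie, r_num, r_den, tb, mid, last = line.rstrip("\n").split("\t")
            records.append(
                LongestIntronRecord(
                    gene_id=gene_id,
                    N=int(N),
                    i=int(i),
                    L=int(L),
                    tie=bool(int(tie)),
                    r=Fraction(int(r_num), int(r_den)),
                    third_bin=tb,
                    is_middle=bool(int(mid)),
                    is_last=bool(int(last)),
                )
            )
    return records
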