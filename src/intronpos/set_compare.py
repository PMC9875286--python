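"""Gene-set composition comparison via per-category 2x2 Fisher's exact tests.

A query gene set's longest-intron position categories are compared
against a reference collection: for each category a 2x2 table
[[query in, query out], [reference in, reference out]] is tested
two-sided.  The query is treated as an independent sample; overlapping
genes are not subtracted from the reference.
"""

from __future__ import annotations

import logging
from typing import Sequence

from scipy import stats

from .core_stats import filter_records, record_in_category
from .models import CATEGORIES, GeneModel, LongestIntronRecord, SetComparison

logger = logging.getLogger(__name__)

DEFAULT_CATEGORIES = CATEGORIES  # the nine reported rows


def build_contingency(
    reference: Sequence[LongestIntronRecord],
    query: Sequence[LongestIntronRecord],
    category: str,
    min_introns: int = 3,
) -> tuple[tuple[int, int], tuple[int, int]]:
    """2x2 counts [[a,b],[c,d]]: rows {query, reference}, cols {in, not in}."""
    ref = filter_records(reference, min_introns)
    qry = filter_records(query, min_introns)
    if not ref or not qry:
        raise ValueError("empty query or reference after min_introns filter")
    a = sum(record_in_category(r, category) for r in qry)
    c = sum(record_in_category(r, category) for r in ref)
    return ((a, len(qry) - a), (c, len(ref) - c))


def fisher_two_sided(table) -> tuple[float, bool]:
    """Two-sided Fisher's exact p for a 2x2 table.

    Returns ``(p, zero_margin)``; a table with an all-zero margin is
    uninformative and reported as p = 1 with the flag set.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("negative count in contingency table")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return 1.0, True
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    return p, False


def odds_ratio(table) -> float | None:
    (a, b), (c, d) = table
    if b * c == 0:
        return None
    return (a * d) / (b * c)


def compare_sets(
    reference: Sequence[LongestIntronRecord],
    query: Sequence[LongestIntronRecord],
    categories: Sequence[str] = DEFAULT_CATEGORIES,
    min_introns: int = 3,
) -> list[SetComparison]:
    """One per-category Fisher comparison for each requested category.

    Raw p-values mirror the reported analysis; a Bonferroni column over
    the requested categories is added for transparency.
    """
    out = []
    m = len(categories)
    for cat in categories:
        table = build_contingency(reference, query, cat, min_introns)
        (a, b), (c, d) = table
        p, zero = fisher_two_sided(table)
        out.append(
            SetComparison(
                category=cat,
                table=table,
                query_pct=100.0 * a / (a + b),
                reference_pct=100.0 * c / (c + d),
                odds_ratio=odds_ratio(table),
                p=p,
                p_bonferroni=min(1.0, p * m),
                zero_margin=zero,
            )
        )
    return out


def subset_by_symbols(
    genes: Sequence[GeneModel], symbols: set[str]
) -> list[GeneModel]:
    """Genes whose symbol is in ``symbols`` (exact, case-sensitive match)."""
    matched = [g for g in genes if g.symbol in symbols]
    unmatched = symbols - {g.symbol for g in matched}
    if unmatched:
        logger.info(
            "subset_by_symbols: %d query symbol(s) not in collection (dropped)",
            len(unmatched),
        )
    return matched
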