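"""Expression stratification by longest-intron position category.

Per-gene tissue expression (HPA-style consensus nTPM) is joined with
longest-intron position categories; each tissue is tested for
expression differences across position groups with Kruskal-Wallis and
all pairwise two-sided Mann-Whitney tests, and significant pairs are
counted across tissues with their direction (by group median).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_stats import filter_records, mann_whitney_two_sided, record_in_category
from .models import (
    ABSOLUTE_GROUPS,
    THIRD_BINS,
    ExpressionTable,
    LongestIntronRecord,
    TissueStrataResult,
)

logger = logging.getLogger(__name__)

EXPRESSION_COLUMNS = ["Gene", "Gene name", "Tissue", "nTPM"]


def read_expression(path: str | Path) -> ExpressionTable:
    """Read a long-format HPA-style TSV (Gene, Gene name, Tissue, nTPM)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EXPRESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if df.duplicated(subset=["Gene name", "Tissue"]).any():
        raise ValueError(f"{path}: duplicate (gene, tissue) rows")
    if (df["nTPM"] < 0).any():
        raise ValueError(f"{path}: negative nTPM")
    pivot = df.pivot(index="Gene name", columns="Tissue", values="nTPM")
    if pivot.isna().any().any():
        pivot = pivot.dropna(how="any")
        logger.info("read_expression: dropped genes with incomplete tissue coverage")
    return ExpressionTable(pivot)


def write_expression(
    table: ExpressionTable, path: str | Path, gene_ids: dict[str, str] | None = None
) -> None:
    """Write back to the long-format dialect (round-trip safe)."""
    long = table.values.reset_index().melt(
        id_vars="Gene name", var_name="Tissue", value_name="nTPM"
    )
    long["Gene"] = (
        long["Gene name"].map(gene_ids) if gene_ids else long["Gene name"]
    )
    long = long[EXPRESSION_COLUMNS].sort_values(["Gene name", "Tissue"], kind="stable")
    long.to_csv(path, sep="\t", index=False)


def _category_of(rec: LongestIntronRecord, grouping: str) -> str:
    if grouping == "absolute":
        return f"I{rec.i}" if rec.i <= 5 else ">I5"
    return rec.third_bin


def stratify(
    records: Sequence[LongestIntronRecord],
    expr: ExpressionTable,
    grouping: str = "absolute",
    min_introns: int = 3,
    symbol_of: dict[str, str] | None = None,
) -> list[TissueStrataResult]:
    """Per-tissue rank tests of nTPM across position groups.

    Groups are {I1..I5, >I5} (absolute) or the three thirds (relative).
    Genes absent from the expression table are dropped with a logged
    count.  ``symbol_of`` optionally maps record gene_ids to expression
    symbols.  Tissues with fewer than two groups of two genes are
    flagged and skipped.
    """
    if grouping not in ("absolute", "relative"):
        raise ValueError(f"unknown grouping {grouping!r}")
    groups = ABSOLUTE_GROUPS if grouping == "absolute" else THIRD_BINS
    kept = filter_records(records, min_introns)
    gene_cat: dict[str, str] = {}
    n_missing = 0
    for rec in kept:
        sym = symbol_of.get(rec.gene_id, rec.gene_id) if symbol_of else rec.gene_id
        if sym in expr.values.index:
            gene_cat[sym] = _category_of(rec, grouping)
        else:
            n_missing += 1
    if n_missing:
        logger.info("stratify: %d record(s) absent from expression table", n_missing)
    results = []
    for tissue in expr.tissues:
        col = expr.values[tissue]
        samples = {
            g: col.loc[[s for s, c in gene_cat.items() if c == g]].to_numpy()
            for g in groups
        }
        samples = {g: v for g, v in samples.items() if v.size > 0}
        usable = [g for g, v in samples.items() if v.size >= 2]
        if len(usable) < 2:
            logger.info("stratify: tissue %s skipped (insufficient groups)", tissue)
            continue
        kw_vectors = [samples[g] for g in usable]
        if np.ptp(np.concatenate(kw_vectors)) == 0:
            kw_p = 1.0  # no variation anywhere: trivially null
        else:
            kw_p = float(stats.kruskal(*kw_vectors).pvalue)
        pairs = [
            (g1, g2)
            for a, g1 in enumerate(usable)
            for g2 in usable[a + 1:]
        ]
        p_raw = {
            pair: mann_whitney_two_sided(samples[pair[0]], samples[pair[1]])
            for pair in pairs
        }
        m = len(pairs)
        results.append(
            TissueStrataResult(
                tissue=tissue,
                grouping=grouping,
                group_n={g: int(samples[g].size) for g in usable},
                group_median={g: float(np.median(samples[g])) for g in usable},
                kw_p=kw_p,
                p_raw=p_raw,
                p_bonferroni={p: min(1.0, v * m) for p, v in p_raw.items()},
                direction={
                    (g1, g2): int(
                        np.sign(np.median(samples[g1]) - np.median(samples[g2]))
                    )
                    for g1, g2 in pairs
                },
            )
        )
    return results


def count_significant_pairs(
    results: Sequence[TissueStrataResult], alpha: float = 0.05
) -> pd.DataFrame:
    """Tissue counts of directed significant pairs (raw p < alpha).

    Each unordered tested pair contributes to the ordered pair whose
    first group has the higher median; ties in medians are not counted.
    Returns a DataFrame with columns higher, lower, n_tissues.
    """
    if not list(results):
        raise ValueError("no stratification results")
    counts: dict[tuple[str, str], int] = {}
    for res in results:
        for (g1, g2), p in res.p_raw.items():
            if not (p < alpha):
                continue
            d = res.direction[(g1, g2)]
            if d == 0:
                continue
            key = (g1, g2) if d > 0 else (g2, g1)
            counts[key] = counts.get(key, 0) + 1
    rows = [
        {"higher": hi, "lower": lo, "n_tissues": n}
        for (hi, lo), n in sorted(counts.items(), key=lambda kv: -kv[1])
    ]
    return pd.DataFrame(rows, columns=["higher", "lower", "n_tissues"])
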