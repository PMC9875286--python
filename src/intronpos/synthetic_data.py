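"""Seeded generators for gene models, enriched gene sets and expression tables.

The generator emulates the statistical structure of human protein-coding
gene architecture that the analysis assumes:

* intron counts: a shifted negative binomial (support >= 1 for
  intron-bearing genes) with dispersion solved numerically so the
  intron-bearing counts hit a target mean of 12.6 and median of 9 —
  right-skewed, with an excess of genes with few introns;
* an intronless fraction of ~2.3%;
* intron lengths: log-normal with a genome-wide median of ~1.6 kb, a
  first-intron multiplier (first introns run about twice as long as the
  rest) and a mild geometric decay of the median with intron index;
* exon lengths: log-normal with median 150 bp;
* category-enriched gene sets (weighted sampling without replacement);
* tissue expression: log-normal nTPM around a median of 10 with
  per-category multiplicative group shifts.

All outputs are deterministic given the seed: one RNG stream per
generation call, sub-seeds derived by fixed offsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_stats import longest_intron, record_in_category
from .expression_strata import EXPRESSION_COLUMNS
from .models import ExpressionTable, GeneModel

_INTERGENIC_GAP = 10_000
_CHROM = "chrS"


@dataclass
class SynthParams:
    """Generation parameters; defaults are the study-scale calibration."""

    n_genes: int = 1000
    intronless_prob: float = 0.023
    count_mean: float = 12.6          # mean introns over intron-bearing genes
    count_median: float = 9.0         # median introns over intron-bearing genes
    length_median: float = 1600.0     # bp, genome-wide intron median
    length_sigma: float = 1.1         # log-sd of intron lengths
    first_intron_multiplier: float = 2.2
    positional_decay: float = 0.02    # per-index geometric decay of the median
    exon_median: float = 150.0
    exon_sigma: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.intronless_prob <= 1:
            raise ValueError("intronless_prob must be in [0,1]")
        if self.first_intron_multiplier < 1:
            raise ValueError("first_intron_multiplier must be >= 1")
        if not 0 <= self.positional_decay < 1:
            raise ValueError("positional_decay must be in [0,1)")
        if self.length_sigma <= 0 or self.exon_sigma <= 0:
            raise ValueError("log-sd parameters must be > 0")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.count_mean <= self.count_median / 2 or self.count_median < 1:
            raise ValueError("count targets out of range")


def solve_count_dispersion(mean: float, median: float) -> float:
    """Dispersion r of the shifted negative binomial hitting both targets.

    The shifted count is 1 + NB(r, p) with p = r/(r + mu), mu = mean - 1.
    The NB median is a nondecreasing step function of r at fixed mean, so
    the r-interval where the median equals the target is found by
    bisection on its two edges and the midpoint is returned.
    """
    mu = mean - 1.0
    med_target = median - 1.0

    def nb_median(r: float) -> float:
        return float(stats.nbinom.ppf(0.5, r, r / (r + mu)))

    lo, hi = 1e-3, 1e3
    if not nb_median(lo) <= med_target <= nb_median(hi):
        raise ValueError("median target unreachable at this mean")

    def edge(target_median: float) -> float:
        # smallest r with nb_median(r) >= target_median
        a, b = lo, hi
        for _ in range(200):
            m = math.sqrt(a * b)
            if nb_median(m) >= target_median:
                b = m
            else:
                a = m
        return b

    return 0.5 * (edge(med_target) + edge(med_target + 1.0))


def generate_genes(params: SynthParams) -> list[GeneModel]:
    """Generate a seeded collection of gene models with GFF3-writable coordinates.

    Intron k (1-based, transcription order) is log-normal with median
    ``length_median * (1 - decay)^(k-1)``, multiplied by the
    first-intron multiplier for k = 1; lengths are rounded up and >= 1.
    Genes are laid on one synthetic chromosome on alternating strands.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_genes
    intronless = rng.random(n) < params.intronless_prob
    r = solve_count_dispersion(params.count_mean, params.count_median)
    mu = params.count_mean - 1.0
    counts = 1 + stats.nbinom.rvs(r, r / (r + mu), size=n, random_state=rng)
    counts[intronless] = 0

    total_introns = int(counts.sum())
    z_intron = rng.normal(size=total_introns)
    z_exon = rng.normal(size=int(counts.sum() + n))

    models: list[GeneModel] = []
    pos = 1
    i_off = 0
    e_off = 0
    for g in range(n):
        N = int(counts[g])
        ks = np.arange(N)
        med = params.length_median * (1.0 - params.positional_decay) ** ks
        if N:
            med[0] *= params.first_intron_multiplier
        introns = np.ceil(
            med * np.exp(params.length_sigma * z_intron[i_off:i_off + N])
        ).astype(int)
        introns = np.maximum(introns, 1)
        i_off += N
        exons = np.ceil(
            params.exon_median
            * np.exp(params.exon_sigma * z_exon[e_off:e_off + N + 1])
        ).astype(int)
        exons = np.maximum(exons, 1)
        e_off += N + 1

        strand = "+" if g % 2 == 0 else "-"
        # genomic order: transcription order on +, reversed on -
        ex_g = exons if strand == "+" else exons[::-1]
        in_g = introns if strand == "+" else introns[::-1]
        intervals = []
        cursor = pos
        for idx in range(N + 1):
            intervals.append((cursor, cursor + int(ex_g[idx]) - 1))
            cursor += int(ex_g[idx])
            if idx < N:
                cursor += int(in_g[idx])
        pos = cursor + _INTERGENIC_GAP

        name = f"SYNG{g + 1:06d}"
        models.append(
            GeneModel(
                gene_id=name,
                symbol=name,
                transcript_id=f"{name}.t1",
                strand=strand,
                exons=intervals,
                intron_lengths=[int(x) for x in introns],
            )
        )
    return models


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write models as GFF3 with a canonical-tagged mRNA per gene."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            start = m.exons[0][0]
            end = m.exons[-1][1]
            fh.write(
                f"{_CHROM}\tintronpos\tgene\t{start}\t{end}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id};Name={m.symbol};biotype=protein_coding\n"
            )
            fh.write(
                f"{_CHROM}\tintronpos\tmRNA\t{start}\t{end}\t.\t{m.strand}\t.\t"
                f"ID={m.transcript_id};Parent={m.gene_id};tag=MANE_Select\n"
            )
            for k, (s, e) in enumerate(m.exons, start=1):
                fh.write(
                    f"{_CHROM}\tintronpos\texon\t{s}\t{e}\t.\t{m.strand}\t.\t"
                    f"ID={m.transcript_id}.e{k};Parent={m.transcript_id}\n"
                )


def write_gene_set(symbols: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for s in sorted(symbols):
            fh.write(s + "\n")


def plant_gene_set(
    genes: Sequence[GeneModel],
    target_category: str,
    enrichment_fold: float,
    set_size: int,
    seed: int,
) -> set[str]:
    """Sample a gene set enriched for one longest-intron category.

    Sampling is without replacement with weights multiplied by
    ``enrichment_fold`` for genes whose longest intron falls in
    ``target_category`` (genes with under three introns never qualify).
    """
    if enrichment_fold < 1:
        raise ValueError("enrichment_fold must be >= 1")
    if set_size > len(genes):
        raise ValueError("set_size exceeds available genes")
    in_cat = np.array(
        [
            g.n_introns >= 3 and record_in_category(longest_intron(g), target_category)
            for g in genes
        ]
    )
    weights = np.where(in_cat, enrichment_fold, 1.0)
    probs = weights / weights.sum()
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(genes), size=set_size, replace=False, p=probs)
    return {genes[k].symbol for k in idx}


def generate_expression(
    genes: Sequence[GeneModel],
    group_effects: dict[str, float] | None,
    n_tissues: int,
    seed: int,
    baseline_median: float = 10.0,
    sigma: float = 1.0,
) -> ExpressionTable:
    """Log-normal nTPM per (gene, tissue) with per-category multipliers.

    A gene's baseline median is multiplied by the effect of every
    category its longest intron belongs to (intronless genes stay at
    baseline).  ``sigma`` is the log-sd of the tissue noise and must be
    positive.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    effects = group_effects or {}
    if any(v <= 0 for v in effects.values()):
        raise ValueError("group effect multipliers must be > 0")
    mult = np.ones(len(genes))
    for gi, g in enumerate(genes):
        if g.n_introns == 0:
            continue
        rec = longest_intron(g)
        for cat, fold in effects.items():
            if record_in_category(rec, cat):
                mult[gi] *= fold
    rng = np.random.default_rng(seed)
    z = rng.normal(size=(len(genes), n_tissues))
    values = baseline_median * mult[:, None] * np.exp(sigma * z)
    df = pd.DataFrame(
        values,
        index=pd.Index([g.symbol for g in genes], name="Gene name"),
        columns=pd.Index([f"tissue_{t + 1:02d}" for t in range(n_tissues)], name="Tissue"),
    )
    return ExpressionTable(df)


def write_expression_tsv(table: ExpressionTable, path: str | Path) -> None:
    """Write an HPA-style long-format TSV (Gene, Gene name, Tissue, nTPM)."""
    long = table.values.reset_index().melt(
        id_vars="Gene name", var_name="Tissue", value_name="nTPM"
    )
    long["Gene"] = long["Gene name"]
    long = long[EXPRESSION_COLUMNS].sort_values(
        ["Gene name", "Tissue"], kind="stable"
    )
    long.to_csv(path, sep="\t", index=False, float_format="%.4f")


def make_fixture_study(
    out_dir: str | Path,
    params: SynthParams,
    set_size: int = 100,
    planted_category: str = "third",
    enrichment_fold: float = 3.0,
    n_tissues: int = 10,
) -> dict[str, Path]:
    """Materialize a complete toy study: annotation, length table, two gene sets, expression."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from .annotation_io import write_length_table

    genes = generate_genes(params)
    paths = {
        "gff3": out / "genes.gff3",
        "length_table": out / "lengths.tsv",
        "set_null": out / "geneset_null.txt",
        "set_planted": out / "geneset_planted.txt",
        "expression": out / "expression.tsv",
    }
    write_gff3(genes, paths["gff3"])
    write_length_table(genes, paths["length_table"])
    write_gene_set(
        plant_gene_set(genes, planted_category, 1.0, set_size, params.seed + 1),
        paths["set_null"],
    )
    write_gene_set(
        plant_gene_set(
            genes, planted_category, enrichment_fold, set_size, params.seed + 2
        ),
        paths["set_planted"],
    )
    write_expression_tsv(
        generate_expression(genes, None, n_tissues, params.seed + 3),
        paths["expression"],
    )
    return paths
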