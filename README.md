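# intronpos

Statistics of **longest-intron position** in protein-coding genes.

Most eukaryotic genes carry their longest intron near the 5′ end — long
first introns are enriched in regulatory elements (CpG islands, chromatin
marks, transcription motifs) and are implicated in intron-mediated
enhancement of expression. But "the first intron is the longest" is only
part of the picture: a substantial fraction of genes carry their longest
intron in the middle or at the end of the transcript, and that position
can track biological function and expression. `intronpos` is a small
pipeline for quantifying exactly that, aimed at anyone doing
gene-architecture analysis from standard annotation files.

For each gene with introns numbered 1…N in transcription direction, the
pipeline locates the longest intron (index *i*, length *L*, 5′-most on
ties) and its **relative position** *r = i/N*, kept as an exact rational.
It then reports, over a gene collection (genes with ≥ 3 introns by
default):

- the **absolute position distribution** — percent of genes with the
  longest intron at I1, I2, …, I5 and pooled >I5;
- the **relative position distribution** — thirds *r* ∈ (0, ⅓],
  (⅓, ⅔], (⅔, 1], decided in integer arithmetic (3·i vs N, 2N), plus
  overlapping "middle" (*r* = ½) and "last" (*i = N*) flags;
- **length medians by position** with pairwise two-sided Mann–Whitney
  tests (raw and Bonferroni);
- an **intron-count summary** (mean, median, max, modal counts,
  Shapiro–Wilk normality);
- **gene-set composition tests**: per category, a 2×2 Fisher's exact
  test of a query set against the reference collection (e.g. do DNA
  repair genes have the longest intron late more often?);
- **expression stratification**: per-tissue Kruskal–Wallis and pairwise
  Mann–Whitney tests of nTPM across position groups, with tissue counts
  of directed significant pairs.

A seeded synthetic-data module generates gene models (shifted
negative-binomial intron counts, log-normal intron/exon lengths with a
first-intron multiplier), category-enriched gene sets, and HPA-style
expression tables, so the full pipeline is testable offline.

## Inputs

- **GFF3/GTF** annotation (one transcript per gene is selected:
  canonical tag such as `MANE_Select`/`Ensembl_canonical` first, then
  longest CDS, then longest transcript), or
- a **length table** TSV: `gene_id<TAB>symbol<TAB>intron_lengths` with
  comma-separated intron lengths in transcription order (empty for
  intronless genes);
- gene sets as one-symbol-per-line text files;
- expression as long-format TSV with columns `Gene`, `Gene name`,
  `Tissue`, `nTPM` (Human Protein Atlas consensus dialect).

## Worked example

```python
from intronpos import (SynthParams, generate_genes, records_from_genes,
                       position_distribution, length_by_position, count_summary)

genes = generate_genes(SynthParams(n_genes=1000, seed=42))
cs = count_summary(genes)
print(f"genes: {cs.n_genes}  intronless: {cs.intronless_pct:.1f}%")
print(f"intron count mean/median/max: {cs.mean:.1f} / {cs.median:.0f} / {cs.max}")

recs = records_from_genes(genes)
dist = position_distribution(recs, min_introns=3)
print(f"genes with >=3 introns: {dist.n_genes}")
print("absolute position %:", {k: round(v, 1) for k, v in dist.absolute_pct.items()})
print("relative thirds %:", {k: round(v, 1) for k, v in dist.relative_pct.items()})
```

prints

```
genes: 1000  intronless: 2.4%
intron count mean/median/max: 12.0 / 8 / 76
genes with >=3 introns: 844
absolute position %: {'I1': 28.7, 'I2': 9.8, 'I3': 11.1, 'I4': 9.1, 'I5': 5.8, '>I5': 35.4}
relative thirds %: {'first': 46.8, 'second': 28.0, 'third': 25.2}
```

i.e. in this synthetic collection 2.4% of genes are intronless, 844 of
1000 genes have at least three introns, and the first intron is the
single most common longest-intron position (28.7% at I1; 46.8% of genes
have the longest intron in the first third of introns) — the qualitative
signature the first-intron length multiplier plants.

The same reports are available from the shell:

```sh
intronpos simulate --n-genes 1000 --seed 42 --out study/
intronpos stats   --input study/lengths.tsv --format table --out report/
intronpos compare --input study/lengths.tsv --format table \
                  --set study/geneset_planted.txt --out report/
intronpos express --input study/lengths.tsv --format table \
                  --expression study/expression.tsv --out report/
```

Each stage writes TSV reports (with `#` metadata lines) plus a JSON
machine twin; identical inputs and configuration give byte-identical
outputs.

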