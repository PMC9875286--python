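# Methods

## The statistic

For a gene whose selected transcript has N ≥ 1 introns, introns are
indexed 1…N in transcription (5′→3′) direction. The longest intron is
located at the smallest index attaining the maximum length; ties are
recorded in a `tie` flag (choosing the 5′-most index is deterministic
and conservative with respect to any 5′ enrichment claim, and the tie
prevalence is reportable). The record holds the absolute index i, the
length L in bp, and the relative position r = i/N stored as an exact
`Fraction`.

The relative position is binned into thirds: (0, 1/3] → first,
(1/3, 2/3] → second, (2/3, 1] → third. The boundaries are evaluated in
integer arithmetic — first ⇔ 3·i ≤ N, second ⇔ N < 3·i ≤ 2·N — never by
floating-point division, so boundary genes (i = 1, N = 3 is exactly
r = 1/3 and lands in the first third) are classified deterministically.
"Middle" (r exactly 1/2; even N only) and "last" (i = N) are flags that
overlap the thirds; the thirds alone partition the collection.

One caveat worth knowing: the thirds are mirror-symmetric around 1/2
only when N is divisible by 3. Under index reversal i → N+1−i, first
and third bins swap exactly on that subcollection, but for example
i = 2 of N = 4 ("second") maps to i = 3 of N = 4 ("third"). The
reversal property test is therefore restricted to genes with 3 | N.

## Collection-level analyses

**Position distribution.** Genes with fewer than `min_introns`
(default 3) introns are excluded first, so two-intron genes cannot
dominate the relative bins. Absolute positions are reported per index
and with all indices above 5 pooled into ">I5"; percentages are over
the filtered gene count and displayed to one decimal.

**Length by position.** Medians of the longest-intron lengths L are
computed per group — absolute {I1…I5, >I5} or relative {first, second,
third, middle, last} — and all pairwise group contrasts are tested with
the two-sided Mann–Whitney U test. Raw p-values are the primary output
(matching common practice for this analysis); Bonferroni-adjusted
values over the tested pairs are emitted alongside. Pairs involving a
group with fewer than two members are flagged insufficient; medians are
still reported from one member.

**Count summary.** Mean, median, maximum (with the gene attaining it),
modal counts, the intronless percentage, and a Shapiro–Wilk test of the
count vector (intron counts in real genomes are strongly right-skewed,
so the test rejects normality at any realistic sample size).

**Gene-set comparison.** For each category (I1…I5, >I5, and the three
thirds) a 2×2 table [[a, b], [c, d]] is built with rows {query set,
reference collection} and columns {in category, not in category}, both
filtered to ≥ 3 introns, and tested with the two-sided Fisher's exact
test (scipy's hypergeometric-enumeration implementation; the test
suite re-derives it by exact `Fraction` enumeration). The query is
treated as an independent sample — overlapping genes are not removed
from the reference — mirroring how such set contrasts are usually run.
Raw p-values are primary; a Bonferroni column over the nine categories
is added for transparency. A table with an empty margin is
uninformative and reported as p = 1 with a flag. Symbol matching is
exact and case-sensitive; unmatched query symbols are logged and
dropped.

**Expression stratification.** A long-format consensus expression table
(Gene, Gene name, Tissue, nTPM) is pivoted to genes × tissues;
duplicate (gene, tissue) pairs and negative nTPM are hard errors. Per
tissue, genes are grouped by their longest-intron category ({I1…I5,
>I5} or the thirds) and compared with Kruskal–Wallis plus all pairwise
two-sided Mann–Whitney tests. Because the tests are rank-based, any
strictly monotone transform of nTPM (e.g. log) leaves every p-value
unchanged — this is asserted in the suite. Tissues with fewer than two
groups of two genes are skipped with a log message. Significant pairs
(raw p < α, default 0.05) are counted across tissues; the direction of
a pair is decided by the group medians, and median ties are not
counted.

## Numerical choices

- Mann–Whitney uses scipy's `method="auto"`: the exact null
  distribution for small tie-free samples (the suite checks exact
  agreement with full-relabelling permutation for group sizes ≤ 8),
  the tie-corrected normal approximation otherwise. A pooled sample
  with zero variance short-circuits to p = 1.
- Intron length from 1-based inclusive exon intervals (s1,e1),(s2,e2)
  is s2 − e1 − 1; abutting or overlapping exons are a hard error naming
  the gene. UTR exons count as exons, so intron positions are
  transcript-wide, not CDS-only. No minimum intron length filter is
  applied.
- Transcript selection prefers a canonical tag (default list
  `MANE_Select`, `Ensembl_canonical`, `canonical`, matched against
  attribute keys and `tag=` values), then longest total CDS, then
  longest transcript, ties broken by lexicographic transcript id.

## The synthetic generator

The generator emulates the gene-architecture features the analysis
depends on; defaults are the study-scale calibration:

| parameter | default | meaning |
|---|---|---|
| `intronless_prob` | 0.023 | fraction of intronless genes |
| `count_mean` / `count_median` | 12.6 / 9 | intron count over intron-bearing genes |
| `length_median` | 1,600 bp | log-normal intron-length median |
| `length_sigma` | 1.1 | log-sd of intron lengths |
| `first_intron_multiplier` | 2.2 | first-intron median multiplier |
| `positional_decay` | 0.02 | per-index geometric decay of the median |
| `exon_median` / `exon_sigma` | 150 bp / 0.6 | exon length distribution |

Intron counts are a shifted negative binomial (support ≥ 1) whose
dispersion is solved numerically so that the count distribution hits
both the mean and the median target — the family is a modelling choice;
only the mean/median/max and the right skew are calibration anchors.
Intron k is log-normal with median `length_median·(1−decay)^(k−1)`,
multiplied by the first-intron multiplier for k = 1, rounded up and
≥ 1 bp. Genes are laid on one synthetic chromosome on alternating
strands with 10 kb intergenic gaps, giving GFF3-writable coordinates
that round-trip losslessly through the annotation parser. Gene symbols
are `SYNG000001`-style to avoid collision with real symbols. Planted
gene sets are drawn without replacement with weights multiplied by an
enrichment fold for genes in the target category; expression tables are
log-normal nTPM (median 10, log-sd 1.0) times per-category group
multipliers. Every generator call uses a single explicitly seeded RNG
stream; identical parameters and seed give byte-identical output files.

What the generator does **not** emulate: sequence content, splice-site
structure, correlations between intron length and count, gene-family
structure, realistic tissue covariance, or dependence between
expression level and gene architecture beyond the planted category
effects. Passing tests therefore demonstrate correctness of the
statistical machinery and its calibration/power under the stated
generative model, not biological claims about real genomes; analyses of
real data enter through the GFF3/GTF, length-table, gene-set and
expression readers.

## Problem sizes in the suite

The property suite uses 10,000-gene collections for calibration checks
(count mean within ±0.5, intronless fraction, first-intron-multiplier
monotonicity, positional uniformity at multiplier 1), a 2,000-gene
reference with 100 planted 100-gene sets for gene-set detection power
at α = 0.01, and 60-genes-per-group expression panels over 100
synthetic tissues for type-I calibration (expected ≈ 5% of raw
pairwise tests at p < .05) and power under a ×4 group shift. These
sizes make the statistical assertions stable across seeds while keeping
the whole suite under a minute.

## Known limitations

- The exact-reproduction path for a published gene table requires that
  table as a length-table TSV input; no network retrieval is performed
  by design.
- GSEA/term-enrichment analysis is out of scope; only contingency-based
  set comparison is implemented.
- Fisher odds ratios are undefined (reported as NA) when b·c = 0.
- The "middle" flag requires r = 1/2 exactly, so odd-N
  genes can never be "middle".
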