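from __future__ import annotations

from fractions import Fraction

import numpy as np
import pytest

from intronpos.core_stats import (
    IntronlessGene,
    categorize_relative,
    count_summary,
    filter_records,
    length_by_position,
    longest_intron,
    mann_whitney_two_sided,
    position_distribution,
    read_records,
    records_from_genes,
    write_records,
)
from conftest import make_gene
from _oracles import categorize_oracle, count_positions_oracle


class TestLongestIntron:
    @pytest.mark.parametrize(
        "lengths,i,r,third_bin,is_middle,is_last,tie",
        [
            ([100], 1, Fraction(1), "third", False, True, False),
            ([5, 9, 2], 2, Fraction(2, 3), "second", False, False, False),
            ([7, 7, 3], 1, Fraction(1, 3), "first", False, False, True),
            ([10, 10, 800, 20], 3, Fraction(3, 4), "third", False, False, False),
        ],
    )
    def test_examples(self, lengths, i, r, third_bin, is_middle, is_last, tie):
        rec = longest_intron(make_gene("G", lengths))
        assert (rec.i, rec.r, rec.third_bin) == (i, r, third_bin)
        assert (rec.is_middle, rec.is_last, rec.tie) == (is_middle, is_last, tie)
        assert rec.N == len(lengths)
        assert rec.L == max(lengths)

    def test_intronless_gene_signalled(self):
        with pytest.raises(IntronlessGene):
            longest_intron(make_gene("G", []))

    def test_records_from_genes_skips_intronless(self, toy_genes):
        recs = records_from_genes(toy_genes)
        assert len(recs) == 5
        assert all(r.N >= 1 for r in recs)


class TestCategorizeRelative:
    def test_boundary_third_counts_as_first(self):
        assert categorize_relative(1, 3) == ("first", False, False)

    def test_half_is_second_and_middle(self):
        assert categorize_relative(2, 4) == ("second", True, False)

    @pytest.mark.parametrize("i,N", [(0, 3), (4, 3), (-1, 5)])
    def test_out_of_range_rejected(self, i, N):
        with pytest.raises(ValueError):
            categorize_relative(i, N)

    def test_exhaustive_agreement_with_rational_oracle(self):
        for N in range(1, 61):
            for i in range(1, N + 1):
                assert categorize_relative(i, N) == categorize_oracle(i, N), (i, N)


class TestPositionDistribution:
    def test_all_first(self):
        recs = [longest_intron(make_gene(f"G{k}", [900, 1, 2])) for k in range(3)]
        dist = position_distribution(recs)
        assert dist.absolute_pct["I1"] == 100.0
        assert dist.relative_pct["first"] == 100.0

    def test_counts_match_recount_oracle(self, genes_2k):
        recs = records_from_genes(genes_2k)
        dist = position_distribution(recs, min_introns=3)
        n, oracle = count_positions_oracle(recs, min_introns=3)
        assert dist.n_genes == n
        for cat in ("I1", "I2", "I3", "I4", "I5", ">I5"):
            assert dist.absolute_counts[cat] == oracle[cat]
        for cat in ("first", "second", "third"):
            assert dist.relative_counts[cat] == oracle[cat]
        assert dist.middle_count == oracle["middle"]
        assert dist.last_count == oracle["last"]

    def test_third_bins_partition_and_percentages_sum(self, genes_2k):
        dist = position_distribution(records_from_genes(genes_2k))
        assert sum(dist.relative_counts.values()) == dist.n_genes
        assert sum(dist.absolute_counts.values()) == dist.n_genes
        assert sum(dist.relative_pct.values()) == pytest.approx(100.0)

    def test_reversal_swaps_first_and_third_bins(self, genes_2k):
        """Reversing intron order maps index i to N+1-i on tie-free genes.

        The bin boundaries (0,1/3], (1/3,2/3], (2/3,1] are mirror-symmetric
        around 1/2 only when N is divisible by 3 (for N=4, i=2 is "second"
        but its mirror i=3 is "third"), so the swap is checked there.
        """
        tie_free = [
            g
            for g in genes_2k
            if g.n_introns >= 3
            and g.n_introns % 3 == 0
            and g.intron_lengths.count(max(g.intron_lengths)) == 1
        ]
        fwd = position_distribution(records_from_genes(tie_free))
        rev_genes = [
            make_gene(g.gene_id, g.intron_lengths[::-1]) for g in tie_free
        ]
        rev = position_distribution(records_from_genes(rev_genes))
        assert rev.relative_counts["first"] == fwd.relative_counts["third"]
        assert rev.relative_counts["third"] == fwd.relative_counts["first"]
        assert rev.relative_counts["second"] == fwd.relative_counts["second"]

    def test_raising_filter_never_increases_n(self, genes_2k):
        recs = records_from_genes(genes_2k)
        sizes = [len(filter_records(recs, m)) for m in range(0, 10)]
        assert sizes == sorted(sizes, reverse=True)

    def test_empty_after_filter_is_error(self):
        recs = [longest_intron(make_gene("G", [5]))]
        with pytest.raises(ValueError):
            position_distribution(recs, min_introns=3)


class TestLengthByPosition:
    def test_identical_groups_give_p_one(self):
        p = mann_whitney_two_sided([3.0, 5.0, 9.0, 9.0], [3.0, 5.0, 9.0, 9.0])
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_medians_and_insufficient_flag(self):
        genes = [
            make_gene("A", [1000, 1, 2]),
            make_gene("B", [2000, 1, 2]),
            make_gene("C", [3000, 1, 2]),
            make_gene("D", [1, 5000, 2]),  # lone I2 member
        ]
        lbp = length_by_position(records_from_genes(genes), "absolute")
        assert lbp.median["I1"] == 2000.0
        assert lbp.median["I2"] == 5000.0
        assert ("I1", "I2") in lbp.insufficient
        assert np.isnan(lbp.p_raw[("I1", "I2")])

    def test_relative_grouping_includes_overlapping_flags(self, genes_2k):
        recs = records_from_genes(genes_2k)
        lbp = length_by_position(recs, "relative")
        assert lbp.groups == ("first", "second", "third", "middle", "last")
        kept = filter_records(recs, 3)
        assert lbp.n["middle"] == sum(r.is_middle for r in kept)
        assert lbp.n["last"] == sum(r.is_last for r in kept)

    def test_bonferroni_never_below_raw(self, genes_2k):
        lbp = length_by_position(records_from_genes(genes_2k), "absolute")
        for pair, p in lbp.p_raw.items():
            if not np.isnan(p):
                assert lbp.p_bonferroni[pair] >= p - 1e-15


class TestCountSummary:
    def test_small_example(self):
        genes = [make_gene("A", []), make_gene("B", [9]), make_gene("C", [1, 2])]
        cs = count_summary(genes)
        assert cs.intronless_pct == pytest.approx(100 / 3)
        assert cs.median == 1.0
        assert cs.max == 2
        assert cs.argmax_gene_id == "C"

    def test_against_streaming_oracle(self, genes_2k):
        cs = count_summary(genes_2k)
        # independent accumulation
        total = n = zeros = 0
        biggest = -1
        for g in genes_2k:
            total += g.n_introns
            n += 1
            zeros += g.n_introns == 0
            biggest = max(biggest, g.n_introns)
        assert cs.mean == pytest.approx(total / n)
        assert cs.max == biggest
        assert cs.intronless_pct == pytest.approx(100 * zeros / n)
        assert 0 < cs.shapiro_p < 1 or cs.shapiro_p == 0.0

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            count_summary([])


class TestRecordsIO:
    def test_round_trip(self, tmp_path, genes_2k):
        recs = records_from_genes(genes_2k[:200])
        p = tmp_path / "records.tsv"
        write_records(recs, p)
        assert read_records(p) == recs
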