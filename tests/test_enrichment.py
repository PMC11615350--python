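"""Fold-change computation and the two-threshold enrichment rule."""

import math

import pytest

from chipdiff import classify_enrichment, peak_fold_change, rollup_genes
from chipdiff.consensus import PeakPartition
from chipdiff.coverage import CoverageTrack
from chipdiff.enrichment import (
    EnrichmentCall,
    EnrichmentResult,
    annotate_calls,
    category_counts,
    genomic_distribution,
)
from chipdiff.genome import GenomicInterval

SIZES = {"chr1": 100000}
PEAK = GenomicInterval("chr1", 1000, 2000)


def const_track(value, sizes=SIZES, scale=1.0):
    return CoverageTrack.from_records(
        [(c, 0, n, value) for c, n in sizes.items()], sizes, scale
    )


def empty_partition_with_common(n):
    """Partition stub carrying n common pairs at distinct spans."""
    from chipdiff.consensus import ConsensusPeak

    def cp(start, end):
        return ConsensusPeak(GenomicInterval("chr1", start, end), 2, ())

    common = [(cp(1000 * i + 100, 1000 * i + 500),
               cp(1000 * i + 200, 1000 * i + 600)) for i in range(1, n + 1)]
    return PeakPartition(target="KDM2A", common=common, wt_only=[], ko_only=[])


class TestPeakFoldChange:
    def test_constant_tracks(self):
        fc = peak_fold_change(PEAK, [const_track(6.0)] * 3, const_track(2.0))
        assert fc == pytest.approx(3.0)

    def test_mean_of_per_replicate_ratios(self):
        # ratios 2 and 4 average to 3
        fc = peak_fold_change(
            PEAK, [const_track(4.0), const_track(8.0)], const_track(2.0)
        )
        assert fc == pytest.approx(3.0)

    def test_epsilon_floor_engaged_on_zero_input(self):
        fc = peak_fold_change(
            PEAK, [const_track(1.0)], const_track(0.0), epsilon=0.25
        )
        assert fc == pytest.approx(4.0)

    def test_peak_outside_chrom_bounds_rejected(self):
        bad = GenomicInterval("chr1", 99000, 101000)
        with pytest.raises(ValueError):
            peak_fold_change(bad, [const_track(1.0)], const_track(1.0))

    def test_scaling_invariance(self):
        # multiplying every track by the same constant leaves fc unchanged
        fc1 = peak_fold_change(PEAK, [const_track(5.0)], const_track(2.0))
        fc2 = peak_fold_change(
            PEAK, [const_track(5.0, scale=7.3)], const_track(2.0, scale=7.3)
        )
        assert fc1 == pytest.approx(fc2)


class TestClassifyEnrichment:
    def classify_common(self, pairs, **kw):
        part = empty_partition_with_common(len(pairs))
        return classify_enrichment(part, pairs, [], [], **kw)

    @pytest.mark.parametrize(
        "fc_wt,fc_ko,expected",
        [
            (4.0, 3.0, "WT_enriched"),  # ratio 1.333 > 2^0.23, fc 4 > 3
            (3.0, 4.0, "KO_enriched"),
            (5.0, 5.0, "unclassified"),  # ratio exactly 1
            (3.0, 2.0, "unclassified"),  # fc at boundary: strict inequality
            (2.9, 1.0, "unclassified"),  # fc below threshold despite big ratio
            (4.0, 3.5, "unclassified"),  # ratio 1.143 < 2^0.23 ~ 1.173
        ],
    )
    def test_common_peak_rule(self, fc_wt, fc_ko, expected):
        (call,) = self.classify_common([(fc_wt, fc_ko)]).calls
        assert call.label == expected

    def test_ratio_boundary_exact_and_epsilon_above(self):
        # log2 ratio exactly 0.23 stays unclassified; a hair above flips
        fc_ko = 4.0
        fc_wt_exact = fc_ko * 2 ** 0.23
        (call,) = self.classify_common([(fc_wt_exact, fc_ko)]).calls
        assert call.label == "unclassified"
        (call,) = self.classify_common([(fc_wt_exact * 1.0001, fc_ko)]).calls
        assert call.label == "WT_enriched"

    def test_exclusive_peak_needs_only_fc(self):
        from chipdiff.consensus import ConsensusPeak

        wt_only = [ConsensusPeak(GenomicInterval("chr1", 100, 300), 2, ())] * 2
        part = PeakPartition(target="KDM2A", common=[], wt_only=list(wt_only), ko_only=[])
        res = classify_enrichment(part, [], [2.5, 3.5], [])
        assert [c.label for c in res.calls] == ["unclassified", "WT_enriched"]

    def test_missing_fc_rejected(self):
        part = empty_partition_with_common(2)
        with pytest.raises(ValueError, match="missing|fc"):
            classify_enrichment(part, [(4.0, 1.0)], [], [])

    def test_monotonicity_in_fc_wt(self):
        # raising fc_wt never demotes a WT_enriched common peak
        fc_ko = 2.0
        labels = [
            self.classify_common([(fc_wt, fc_ko)]).calls[0].label
            for fc_wt in [3.1, 4.0, 8.0, 100.0]
        ]
        assert labels == ["WT_enriched"] * 4

    def test_summary_tallies_match_calls(self):
        res = self.classify_common([(4.0, 3.0), (3.0, 4.0), (5.0, 5.0)])
        s = res.summary
        assert s["by_label"]["WT_enriched"] == 1
        assert s["by_label"]["KO_enriched"] == 1
        assert s["by_label"]["unclassified"] == 1
        assert sum(s["by_label"].values()) == len(res.calls)


class TestRollupAndDistribution:
    def _call(self, label, gene_id, start=100):
        return EnrichmentCall(
            peak=GenomicInterval("chr1", start, start + 100), origin="common",
            fc_wt=4.0, fc_ko=1.0, log2_ratio=2.0, label=label, gene_id=gene_id,
        )

    def test_rollup_distinct_genes_le_peaks(self):
        res = EnrichmentResult(
            calls=[
                self._call("WT_enriched", "geneA", 100),
                self._call("WT_enriched", "geneA", 300),
                self._call("WT_enriched", "geneB", 500),
            ]
        )
        roll = rollup_genes(res).set_index("label")
        assert roll.loc["WT_enriched", "n_genes"] == 2
        assert roll.loc["WT_enriched", "n_peaks"] == 3

    def test_rollup_empty_result(self):
        roll = rollup_genes(EnrichmentResult(calls=[])).set_index("label")
        assert (roll["n_peaks"] == 0).all()

    def test_annotate_attaches_nearest_gene(self, small_annotation):
        res = EnrichmentResult(
            calls=[
                EnrichmentCall(
                    peak=GenomicInterval("chr1", 4400, 4600), origin="common",
                    fc_wt=4.0, fc_ko=1.0, log2_ratio=2.0, label="WT_enriched",
                )
            ]
        )
        out = annotate_calls(res, small_annotation)
        call = out.calls[0]
        assert call.gene_id == "geneA"
        assert call.tss_distance == 500
        assert call.region_category == "promoter_tss"

    def test_category_priority_and_fractions_sum_to_one(self, small_annotation):
        class P:
            def __init__(self, chrom, pos):
                self.chrom, self.midpoint = chrom, pos

        peaks = [
            P("chr1", 4500),   # 500 bp from geneA TSS -> promoter
            P("chr1", 14000),  # inside geneB, 6.5 kb from its TSS -> body
            P("chr1", 45000),  # far from everything -> intergenic
        ]
        counts = category_counts(peaks, small_annotation)
        assert counts == {"promoter_tss": 1, "gene_body": 1, "intergenic": 1}
        dist = genomic_distribution({"s1": peaks}, small_annotation)
        assert dist.loc["s1"].sum() == pytest.approx(1.0)
        assert dist.loc["average"].sum() == pytest.approx(1.0)
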