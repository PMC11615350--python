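"""TSS window signal, genotype ratio counts, metagene matrices."""

import numpy as np
import pytest

from chipdiff import (
    Gene,
    GenomeAnnotation,
    GenomicInterval,
    genotype_ratio_counts,
    metagene_matrix,
    tss_window_signal,
)
from chipdiff.coverage import CoverageTrack

SIZES = {"chr1": 100000}


def const_track(value, sizes=SIZES):
    return CoverageTrack.from_records(
        [(c, 0, n, value) for c, n in sizes.items()], sizes
    )


class TestTssWindowSignal:
    def test_constant_track_gives_constant_means(self, small_annotation):
        means = tss_window_signal(const_track(3.0, small_annotation.chrom_sizes),
                                  small_annotation, cgi_only=False)
        assert set(means) == {"geneA", "geneB", "geneC", "geneD"}
        assert all(v == pytest.approx(3.0) for v in means.values())

    def test_cgi_only_restricts_universe(self, small_annotation):
        means = tss_window_signal(const_track(1.0, small_annotation.chrom_sizes),
                                  small_annotation, cgi_only=True)
        assert set(means) == {"geneA", "geneD"}

    def test_minus_strand_window_extends_to_lower_coordinates(self):
        # gene on - strand at [10000, 20000): TSS 19999, window (17499, 19999]
        ann = GenomeAnnotation(
            genes=[Gene("g", GenomicInterval("chr1", 10000, 20000, "-"))],
            chrom_sizes=SIZES,
        )
        track = CoverageTrack.from_records(
            [("chr1", 17500, 20000, 4.0), ("chr1", 20000, 30000, 9.0)], SIZES
        )
        means = tss_window_signal(track, ann, window_bp=2500, cgi_only=False)
        # the window covers exactly the 4.0 step, none of the 9.0 downstream-of-gene step
        assert means["g"] == pytest.approx(4.0)

    def test_window_clipped_at_chromosome_end(self):
        ann = GenomeAnnotation(
            genes=[Gene("g", GenomicInterval("chr1", 99000, 100000, "+"))],
            chrom_sizes=SIZES,
        )
        track = const_track(2.0)
        means = tss_window_signal(track, ann, window_bp=2500, cgi_only=False)
        # only 1 kb is available; the mean is over the clipped span
        assert means["g"] == pytest.approx(2.0)

    def test_nonpositive_window_rejected(self, small_annotation):
        with pytest.raises(ValueError):
            tss_window_signal(const_track(1.0, small_annotation.chrom_sizes),
                              small_annotation, window_bp=0)


class TestGenotypeRatioCounts:
    def test_directional_counting(self):
        wt = {"g1": 2.0, "g2": 1.0, "g3": 3.0}
        ko = {"g1": 1.0, "g2": 2.0, "g3": 3.0}
        rc = genotype_ratio_counts(wt, ko)
        assert (rc.n_lower, rc.n_higher, rc.n_other) == (1, 1, 1)
        row = rc.table.set_index("gene_id").loc["g1"]
        assert row["ratio"] == pytest.approx(0.5)

    def test_zero_wt_mean_excluded_from_both_counts(self):
        rc = genotype_ratio_counts({"g": 0.0}, {"g": 5.0})
        assert (rc.n_lower, rc.n_higher, rc.n_other) == (0, 0, 1)
        assert np.isnan(rc.table["ratio"].iloc[0])

    def test_mismatched_gene_sets_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            genotype_ratio_counts({"a": 1.0}, {"b": 1.0})

    def test_counts_match_brute_force_on_random_table(self, rng):
        genes = [f"g{i}" for i in range(500)]
        wt = {g: float(rng.uniform(0, 3)) for g in genes}
        ko = {g: float(rng.uniform(0, 3)) for g in genes}
        rc = genotype_ratio_counts(wt, ko)
        n_lower = sum(1 for g in genes if wt[g] > 0 and ko[g] / wt[g] < 1)
        n_higher = sum(1 for g in genes if wt[g] > 0 and ko[g] / wt[g] > 1)
        assert (rc.n_lower, rc.n_higher) == (n_lower, n_higher)
        assert rc.n_lower + rc.n_higher + rc.n_other == len(genes)


def make_region(gene_id, tss, strand, chrom="chr1", length=5000):
    if strand == "+":
        return Gene(gene_id, GenomicInterval(chrom, tss, tss + length, "+"))
    return Gene(gene_id, GenomicInterval(chrom, tss - length + 1, tss + 1, "-"))


class TestMetagene:
    def test_constant_track_fills_matrix(self):
        regions = [make_region("g1", 50000, "+")]
        m = metagene_matrix(const_track(2.5), regions, flank_bp=1000, bin_size=50)
        assert m.matrix.shape == (1, 40)
        assert np.allclose(m.matrix, 2.5)

    def test_impulse_lands_in_downstream_bin(self):
        # 300 bp impulse 3 kb downstream of a + strand TSS
        track = CoverageTrack.from_records([("chr1", 53000, 53300, 7.0)], SIZES)
        regions = [make_region("g1", 50000, "+")]
        m = metagene_matrix(track, regions, flank_bp=10000, bin_size=100)
        profile = m.profile
        assert profile.shape == (200,)
        hot = np.nonzero(profile)[0]
        # flank 10 kb / 100 bp = 100 bins upstream; +3 kb = bins 130..132
        assert hot.tolist() == [130, 131, 132]

    def test_minus_strand_impulse_maps_to_same_columns(self):
        # the same 3 kb-downstream impulse on a - strand region lies below
        # the TSS; with TSS 49999 the window is [39999, 59999) and the
        # impulse [46699, 46999) fills pre-reversal bins 67-69, which the
        # orientation flip maps to columns 130-132, as on the + strand
        track = CoverageTrack.from_records([("chr1", 46699, 46999, 7.0)], SIZES)
        regions = [make_region("g1", 49999, "-")]
        m = metagene_matrix(track, regions, flank_bp=10000, bin_size=100)
        hot = np.nonzero(m.profile)[0]
        assert hot.tolist() == [130, 131, 132]

    def test_bin_size_must_divide_span(self):
        with pytest.raises(ValueError):
            metagene_matrix(const_track(1.0), [make_region("g", 50000, "+")],
                            flank_bp=1000, bin_size=300)

    def test_profile_equals_naive_double_loop(self, rng):
        # random steps + random regions vs a per-region, per-bin loop
        recs, pos = [], 0
        while pos < 90000:
            width = int(rng.integers(100, 2000))
            recs.append(("chr1", pos, min(100000, pos + width),
                         float(rng.uniform(0, 5))))
            pos += width
        track = CoverageTrack.from_records(recs, SIZES)
        regions = []
        for i in range(50):
            tss = int(rng.integers(12000, 88000))
            strand = "+" if rng.random() < 0.5 else "-"
            regions.append(make_region(f"g{i}", tss, strand, length=3000))
        flank, bins = 10000, 100
        m = metagene_matrix(track, regions, flank_bp=flank, bin_size=bins)

        def naive_bin(chrom, start, end):
            total = 0.0
            for x in range(start, end):
                if 0 <= x < SIZES[chrom]:
                    for c, s, e, v in recs:
                        if s <= x < e:
                            total += v
                            break
            return total / (end - start)

        expected = np.zeros(2 * flank // bins)
        for g in regions:
            row = np.array([
                naive_bin(g.chrom, g.tss - flank + j * bins,
                          g.tss - flank + (j + 1) * bins)
                for j in range(2 * flank // bins)
            ])
            if g.strand == "-":
                row = row[::-1]
            expected += row
        expected /= len(regions)
        assert np.allclose(m.profile, expected, atol=1e-9)

    def test_strand_flip_symmetry(self, rng):
        """Mirroring the genome and flipping strands leaves profiles unchanged."""
        L = SIZES["chr1"]
        recs, pos = [], 0
        while pos < L:
            width = int(rng.integers(500, 3000))
            end = min(L, pos + width)
            recs.append(("chr1", pos, end, float(rng.uniform(0, 4))))
            pos = end
        track = CoverageTrack.from_records(recs, SIZES)
        mirrored = CoverageTrack.from_records(
            sorted((c, L - e, L - s, v) for c, s, e, v in recs), SIZES
        )
        regions, flipped = [], []
        for i in range(20):
            tss = int(rng.integers(15000, 85000))
            strand = "+" if rng.random() < 0.5 else "-"
            regions.append(make_region(f"g{i}", tss, strand))
            # the mirror of an anchor boundary at position t is L - t
            flipped.append(
                make_region(f"g{i}", L - tss, "-" if strand == "+" else "+")
            )
        m1 = metagene_matrix(track, regions, flank_bp=5000, bin_size=100)
        m2 = metagene_matrix(mirrored, flipped, flank_bp=5000, bin_size=100)
        assert np.allclose(m1.profile, m2.profile, atol=1e-9)

    def test_scale_regions_mode_shape(self):
        regions = [make_region("g1", 50000, "+", length=4000),
                   make_region("g2", 30000, "-", length=7000)]
        m = metagene_matrix(const_track(1.0), regions, mode="scale_regions",
                            flank_bp=2000, bin_size=100, body_bins=50)
        assert m.matrix.shape == (2, 20 + 50 + 20)
        assert np.allclose(m.matrix, 1.0)
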