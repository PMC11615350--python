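"""The synthetic-data generator: determinism, planted structure, emitted files."""

import numpy as np
import pandas as pd
import pytest

from chipdiff import (
    PipelineConfig,
    TruthParams,
    generate_annotation,
    generate_experiment,
    generate_tss_experiment,
    run_from_experiment,
    score_label_recovery,
)
from chipdiff.io import read_bedgraph, read_gene_table, read_narrowpeak
from chipdiff.tss import genotype_ratio_counts, tss_window_signal


SMALL = dict(n_genes=60, n_chroms=2, chrom_len=1_500_000)


def small_truth(n=60):
    third = n // 3
    return TruthParams(
        n_wt_enriched=third, n_ko_enriched=third, n_unchanged=n - 2 * third
    )


class TestGenerateAnnotation:
    def test_exact_cgi_fraction(self):
        ann = generate_annotation(n_genes=100, cgi_fraction=0.6, seed=7)
        assert sum(g.has_cgi for g in ann.genes) == 60

    def test_zero_cgi_fraction(self):
        ann = generate_annotation(n_genes=50, cgi_fraction=0.0, seed=7)
        assert not any(g.has_cgi for g in ann.genes)

    def test_same_seed_reproduces_byte_identical_files(self, tmp_path):
        from chipdiff.io import write_gene_table

        for sub in ("a", "b"):
            ann = generate_annotation(n_genes=40, seed=5)
            (tmp_path / sub).mkdir()
            write_gene_table(ann, tmp_path / sub / "genes.bed")
        assert (tmp_path / "a/genes.bed").read_bytes() == (
            tmp_path / "b/genes.bed"
        ).read_bytes()

    def test_genes_non_overlapping_and_in_bounds(self):
        ann = generate_annotation(n_genes=80, n_chroms=2, seed=3)
        by_chrom = {}
        for g in ann.genes:
            by_chrom.setdefault(g.chrom, []).append(g.interval)
            assert 0 <= g.interval.start < g.interval.end <= ann.chrom_sizes[g.chrom]
        for ivs in by_chrom.values():
            ivs.sort()
            for a, b in zip(ivs, ivs[1:]):
                assert a.end <= b.start

    def test_too_many_genes_rejected(self):
        with pytest.raises(ValueError, match="fit"):
            generate_annotation(n_genes=1000, n_chroms=1, chrom_len=100_000)


class TestGenerateExperiment:
    def test_noise_free_recovery_is_exact(self):
        ann = generate_annotation(seed=3, **SMALL)
        exp = generate_experiment(
            ann, small_truth(), noise_sd=0.0, dropout_rate=0.0, seed=3
        )
        out = run_from_experiment(exp)
        frac, _ = score_label_recovery(exp.truth, out.result)
        assert frac == 1.0

    def test_round_trip_identifiability_across_seeds(self):
        for seed in range(10):
            ann = generate_annotation(seed=seed, **SMALL)
            exp = generate_experiment(
                ann, small_truth(30), noise_sd=0.0, dropout_rate=0.0, seed=seed
            )
            out = run_from_experiment(exp)
            frac, _ = score_label_recovery(exp.truth, out.result)
            assert frac == 1.0, f"seed {seed}"

    def test_single_replicate_sites_removed_by_consensus(self):
        # dropout from two of three replicates leaves single-replicate sites,
        # which the min_reps=2 rule must remove; the truth table records the
        # retained-replicate pattern so the expected removals are countable
        ann = generate_annotation(seed=4, **SMALL)
        exp = generate_experiment(
            ann, small_truth(), noise_sd=0.0, dropout_rate=0.55, seed=4
        )
        out = run_from_experiment(exp)
        truth = exp.truth
        expected_wt = (
            (truth["present_in"].str.contains("WT")) & (truth["n_reps_wt"] >= 2)
        ).sum()
        assert len(out.wt_consensus) == expected_wt

    def test_depth_scales_total_coverage_linearly(self):
        ann = generate_annotation(seed=5, **SMALL)
        e1 = generate_experiment(ann, small_truth(), depth=5.0, noise_sd=0.0,
                                 dropout_rate=0.0, seed=5)
        e2 = generate_experiment(ann, small_truth(), depth=10.0, noise_sd=0.0,
                                 dropout_rate=0.0, seed=5)
        t1 = e1.ip_tracks["WT"][0].total()
        t2 = e2.ip_tracks["WT"][0].total()
        assert t2 == pytest.approx(2 * t1, rel=1e-9)

    def test_emitted_files_parse_cleanly(self, tmp_path):
        import warnings

        ann = generate_annotation(seed=6, **SMALL)
        exp = generate_experiment(ann, small_truth(), seed=6)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            paths = exp.write(tmp_path)
            ann2 = read_gene_table(paths["genes"], paths["cgis"], paths["chrom_sizes"])
            assert len(ann2.genes) == len(ann.genes)
            for gt in ("WT", "KO"):
                for p in paths["peaks"][gt]:
                    read_narrowpeak(p)
                for p in paths["ip_tracks"][gt]:
                    read_bedgraph(p, ann2.chrom_sizes)
                read_bedgraph(paths["input_tracks"][gt], ann2.chrom_sizes)

    def test_cgi_flags_round_trip_through_files(self, tmp_path):
        ann = generate_annotation(n_genes=50, cgi_fraction=0.5, seed=8)
        exp = generate_experiment(ann, small_truth(30), seed=8)
        paths = exp.write(tmp_path)
        ann2 = read_gene_table(paths["genes"], paths["cgis"], paths["chrom_sizes"])
        flags1 = {g.gene_id: g.has_cgi for g in ann.genes}
        flags2 = {g.gene_id: g.has_cgi for g in ann2.genes}
        assert flags1 == flags2

    def test_determinism_same_seed_same_truth_and_tracks(self):
        ann = generate_annotation(seed=9, **SMALL)
        a = generate_experiment(ann, small_truth(), seed=9)
        b = generate_experiment(ann, small_truth(), seed=9)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        assert a.ip_tracks["WT"][0].records() == b.ip_tracks["WT"][0].records()

    def test_invalid_margins_rejected(self):
        with pytest.raises(ValueError):
            TruthParams(enriched_margin=1.0)
        with pytest.raises(ValueError):
            TruthParams(unchanged_margin=1.5)


class TestGenerateTssExperiment:
    def test_noise_free_ratios_recover_planted_values(self):
        ann = generate_annotation(seed=10, **SMALL)
        exp = generate_tss_experiment(ann, noise_sd=0.0, seed=10)
        wt = tss_window_signal(exp.wt_tracks[0], ann, cgi_only=False)
        ko = tss_window_signal(exp.ko_tracks[0], ann, cgi_only=False)
        rc = genotype_ratio_counts(wt, ko)
        planted = exp.truth.set_index("gene_id")["planted_ratio"]
        measured = rc.table.set_index("gene_id")["ratio"]
        assert np.allclose(measured[planted.index], planted, rtol=1e-9)

    def test_planted_lower_fraction_counted(self):
        ann = generate_annotation(seed=11, **SMALL)
        exp = generate_tss_experiment(ann, frac_lower=0.7, noise_sd=0.0, seed=11)
        wt = tss_window_signal(exp.wt_tracks[0], ann, cgi_only=False)
        ko = tss_window_signal(exp.ko_tracks[0], ann, cgi_only=False)
        rc = genotype_ratio_counts(wt, ko)
        n = len(ann.genes)
        assert rc.n_lower == round(0.7 * n)
        assert rc.n_higher == n - round(0.7 * n)
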