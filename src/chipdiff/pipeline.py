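"""End-to-end orchestration of the differential occupancy analysis.

Stages: replicate consensus per genotype -> genotype partition ->
fold-change classification -> gene annotation/rollup -> genomic
distribution + category tests -> nearest-TSS distance KS test -> TSS
downstream-ratio counts -> metagene profiles.  Runs either from an
in-memory :class:`~chipdiff.simulate.SyntheticExperiment` or from files
referenced by a :class:`~chipdiff.config.PipelineConfig`, writing every
table plus a count-chain JSON when an output directory is given.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .consensus import (
    ConsensusPeakSet,
    PeakPartition,
    ReplicatePeakSet,
    consensus_peaks,
    partition_by_genotype,
)
from .coverage import CoverageTrack
from .enrichment import (
    EnrichmentResult,
    annotate_calls,
    category_counts,
    classify_enrichment,
    genomic_distribution,
    peak_fold_change,
    rollup_genes,
)
from .genome import GenomeAnnotation
from .io import read_bedgraph, read_gene_table, read_narrowpeak
from .simulate import SyntheticExperiment
from .stats import category_fdr_test, ks_two_sample
from .tss import RatioCounts, genotype_ratio_counts, metagene_matrix, tss_window_signal

logger = logging.getLogger("chipdiff")


class StageError(RuntimeError):
    """Pipeline failure wrapped with the name of the failing stage."""


@dataclass
class PipelineOutputs:
    wt_consensus: ConsensusPeakSet
    ko_consensus: ConsensusPeakSet
    partition: PeakPartition
    result: EnrichmentResult
    gene_rollup: pd.DataFrame
    count_chain: Dict[str, int]
    distribution: Optional[pd.DataFrame] = None
    category_tests: Optional[pd.DataFrame] = None
    tss_distance_ks: Optional[object] = None
    ratio_counts: Optional[RatioCounts] = None


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def compute_count_chain(
    n_initial: Dict[str, int],
    wt_cons: ConsensusPeakSet,
    ko_cons: ConsensusPeakSet,
    partition: PeakPartition,
    result: EnrichmentResult,
    rollup: pd.DataFrame,
) -> Dict[str, int]:
    """The auditable chain of peak counts through every filter."""
    summary = result.summary
    by_label = summary["by_label"]
    roll = rollup.set_index("label")
    return {
        "initial_wt_peaks": n_initial.get("WT", 0),
        "initial_ko_peaks": n_initial.get("KO", 0),
        "wt_consensus": len(wt_cons),
        "ko_consensus": len(ko_cons),
        "common": len(partition.common),
        "wt_only": len(partition.wt_only),
        "ko_only": len(partition.ko_only),
        "wt_enriched_peaks": by_label["WT_enriched"],
        "ko_enriched_peaks": by_label["KO_enriched"],
        "unclassified_peaks": by_label["unclassified"],
        "wt_enriched_genes": int(roll.loc["WT_enriched", "n_genes"]),
        "ko_enriched_genes": int(roll.loc["KO_enriched", "n_genes"]),
    }


def classify_experiment(
    replicate_peaks: Dict[str, Sequence[ReplicatePeakSet]],
    ip_tracks: Dict[str, Sequence[CoverageTrack]],
    input_tracks: Dict[str, CoverageTrack],
    annotation: Optional[GenomeAnnotation],
    cfg: PipelineConfig,
) -> PipelineOutputs:
    """Consensus -> partition -> fc classification -> annotation/rollup."""
    n_initial = {gt: sum(len(r.peaks) for r in reps) for gt, reps in replicate_peaks.items()}
    wt_cons = consensus_peaks(list(replicate_peaks["WT"]), cfg.min_reps)
    ko_cons = consensus_peaks(list(replicate_peaks["KO"]), cfg.min_reps)
    partition = partition_by_genotype(wt_cons, ko_cons)

    def fc(span, genotype):
        return peak_fold_change(
            span,
            list(ip_tracks[genotype]),
            input_tracks[genotype],
            epsilon=cfg.epsilon,
            mode=cfg.fc_mode,
        )

    fc_common = [
        (fc(partition.common_span(i), "WT"), fc(partition.common_span(i), "KO"))
        for i in range(len(partition.common))
    ]
    fc_wt_only = [fc(p.interval, "WT") for p in partition.wt_only]
    fc_ko_only = [fc(p.interval, "KO") for p in partition.ko_only]
    result = classify_enrichment(
        partition, fc_common, fc_wt_only, fc_ko_only,
        fc_threshold=cfg.fc_threshold,
        ratio_log2_threshold=cfg.ratio_log2_threshold,
    )
    distribution = None
    category_tests = None
    ks = None
    if annotation is not None:
        result = annotate_calls(result, annotation, cfg.promoter_halfwidth)
        sample_sets = {
            f"{gt}_{r.replicate_id}": r.peaks
            for gt, reps in replicate_peaks.items()
            for r in reps
        }
        distribution = genomic_distribution(
            sample_sets, annotation, cfg.promoter_halfwidth
        )
        counts_wt = category_counts(wt_cons.peaks, annotation, cfg.promoter_halfwidth)
        counts_ko = category_counts(ko_cons.peaks, annotation, cfg.promoter_halfwidth)
        category_tests = category_fdr_test(counts_wt, counts_ko)
        wt_d = [c.tss_distance for c in result.calls
                if c.label == "WT_enriched" and c.tss_distance is not None]
        ko_d = [c.tss_distance for c in result.calls
                if c.label == "KO_enriched" and c.tss_distance is not None]
        if wt_d and ko_d:
            ks = ks_two_sample(wt_d, ko_d)
    rollup = rollup_genes(result)
    chain = compute_count_chain(n_initial, wt_cons, ko_cons, partition, result, rollup)
    return PipelineOutputs(
        wt_consensus=wt_cons, ko_consensus=ko_cons, partition=partition,
        result=result, gene_rollup=rollup, count_chain=chain,
        distribution=distribution, category_tests=category_tests,
        tss_distance_ks=ks,
    )


def run_from_experiment(
    exp: SyntheticExperiment, cfg: Optional[PipelineConfig] = None
) -> PipelineOutputs:
    """Run the classification pipeline on an in-memory synthetic experiment."""
    cfg = cfg or PipelineConfig()
    return classify_experiment(
        exp.replicate_peaks, exp.ip_tracks, exp.input_tracks, exp.annotation, cfg
    )


def score_label_recovery(
    truth: pd.DataFrame, result: EnrichmentResult
) -> Tuple[float, pd.DataFrame]:
    """Fraction of planted sites whose pipeline label matches the truth.

    Planted "unchanged" sites are expected to come out "unclassified".
    Sites with no overlapping call (e.g. removed by the consensus rule)
    count as mismatches.  Returns (fraction, per-site table).
    """
    by_chrom: Dict[str, List] = {}
    for c in result.calls:
        by_chrom.setdefault(c.peak.chrom, []).append(c)
    rows = []
    n_match = 0
    for _, row in truth.iterrows():
        expected = "unclassified" if row["label"] == "unchanged" else row["label"]
        found = None
        for c in by_chrom.get(row["chrom"], []):
            if c.peak.start < row["end"] and row["start"] < c.peak.end:
                found = c.label
                break
        match = found == expected
        n_match += match
        rows.append(
            {
                "site_id": row["site_id"],
                "planted": row["label"],
                "expected": expected,
                "recovered": found,
                "match": match,
            }
        )
    frac = n_match / len(truth) if len(truth) else float("nan")
    return frac, pd.DataFrame(rows)


def run_pipeline(cfg: PipelineConfig) -> PipelineOutputs:
    """File-driven end-to-end run; writes the result bundle to disk."""
    annotation = None
    if cfg.genes and cfg.chrom_sizes:
        annotation = _load_annotation(cfg)
    replicate_peaks = _load_peaks(cfg)
    ip_tracks, input_tracks = _load_tracks(cfg, annotation)
    outputs = classify_experiment(
        replicate_peaks, ip_tracks, input_tracks, annotation, cfg
    )
    if cfg.tss_tracks and annotation is not None:
        outputs.ratio_counts = _tss_ratio_stage(cfg, annotation)
    write_outputs(outputs, cfg)
    return outputs


@_stage("load_annotation")
def _load_annotation(cfg: PipelineConfig) -> GenomeAnnotation:
    return read_gene_table(cfg.genes, cfg.cgis, cfg.chrom_sizes)


@_stage("load_peaks")
def _load_peaks(cfg: PipelineConfig) -> Dict[str, List[ReplicatePeakSet]]:
    out: Dict[str, List[ReplicatePeakSet]] = {}
    for gt, paths in cfg.peaks.items():
        out[gt] = [
            ReplicatePeakSet(
                genotype=gt, target=cfg.target, replicate_id=f"{gt}_rep{i}",
                peaks=read_narrowpeak(p),
            )
            for i, p in enumerate(paths, start=1)
        ]
    return out


@_stage("load_tracks")
def _load_tracks(cfg: PipelineConfig, annotation: Optional[GenomeAnnotation]):
    if annotation is not None:
        sizes = annotation.chrom_sizes
    else:
        from .io import read_chrom_sizes

        sizes = read_chrom_sizes(cfg.chrom_sizes)
    ip = {
        gt: [read_bedgraph(p, sizes) for p in paths]
        for gt, paths in cfg.ip_tracks.items()
    }
    inputs = {gt: read_bedgraph(p, sizes) for gt, p in cfg.input_tracks.items()}
    return ip, inputs


@_stage("tss_ratio")
def _tss_ratio_stage(cfg: PipelineConfig, annotation: GenomeAnnotation) -> RatioCounts:
    sizes = annotation.chrom_sizes
    means = {}
    for gt, paths in cfg.tss_tracks.items():
        tracks = [read_bedgraph(p, sizes) for p in paths]
        per_rep = [
            tss_window_signal(t, annotation, cfg.tss_window, cfg.cgi_only_ratio)
            for t in tracks
        ]
        means[gt] = {
            g: float(np.mean([m[g] for m in per_rep])) for g in per_rep[0]
        }
    return genotype_ratio_counts(means["WT"], means["KO"], annotation)


def write_outputs(outputs: PipelineOutputs, cfg: PipelineConfig) -> Path:
    """Write the result bundle (tables, BEDs, count-chain JSON, manifest)."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {}

    def bed(peaks, name):
        path = outdir / name
        with open(path, "w") as fh:
            for p in peaks:
                iv = p.interval
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t{p.support_count}\t.\n")
        manifest[name] = str(path)

    bed(outputs.wt_consensus.peaks, "consensus_WT.bed")
    bed(outputs.ko_consensus.peaks, "consensus_KO.bed")
    bed(outputs.partition.wt_only, "wt_only.bed")
    bed(outputs.partition.ko_only, "ko_only.bed")
    pairs = pd.DataFrame(
        [
            {
                "chrom": wt.interval.chrom,
                "wt_start": wt.interval.start, "wt_end": wt.interval.end,
                "ko_start": ko.interval.start, "ko_end": ko.interval.end,
            }
            for wt, ko in outputs.partition.common
        ]
    )
    pairs.to_csv(outdir / "common_pairs.tsv", sep="\t", index=False)
    manifest["common_pairs.tsv"] = str(outdir / "common_pairs.tsv")
    outputs.result.to_frame().to_csv(outdir / "calls.tsv", sep="\t", index=False)
    manifest["calls.tsv"] = str(outdir / "calls.tsv")
    outputs.gene_rollup.to_csv(outdir / "gene_rollup.tsv", sep="\t", index=False)
    manifest["gene_rollup.tsv"] = str(outdir / "gene_rollup.tsv")
    with open(outdir / "count_chain.json", "w") as fh:
        json.dump(outputs.count_chain, fh, indent=2, sort_keys=True)
    manifest["count_chain.json"] = str(outdir / "count_chain.json")
    if outputs.distribution is not None:
        outputs.distribution.to_csv(outdir / "genomic_distribution.tsv", sep="\t")
        manifest["genomic_distribution.tsv"] = str(outdir / "genomic_distribution.tsv")
    if outputs.category_tests is not None:
        outputs.category_tests.to_csv(
            outdir / "category_tests.tsv", sep="\t", index=False
        )
        manifest["category_tests.tsv"] = str(outdir / "category_tests.tsv")
    if outputs.tss_distance_ks is not None:
        ks = outputs.tss_distance_ks
        pd.DataFrame(
            [{"statistic": ks.statistic, "p_value": ks.p_value,
              "method": ks.method, "n1": ks.n1, "n2": ks.n2}]
        ).to_csv(outdir / "tss_distance_ks.tsv", sep="\t", index=False)
        manifest["tss_distance_ks.tsv"] = str(outdir / "tss_distance_ks.tsv")
    if outputs.ratio_counts is not None:
        rc = outputs.ratio_counts
        rc.table.to_csv(outdir / "tss_ratio_table.tsv", sep="\t", index=False)
        with open(outdir / "tss_ratio_counts.json", "w") as fh:
            json.dump(
                {"n_lower": rc.n_lower, "n_higher": rc.n_higher, "n_other": rc.n_other},
                fh, indent=2,
            )
        manifest["tss_ratio_table.tsv"] = str(outdir / "tss_ratio_table.tsv")
        manifest["tss_ratio_counts.json"] = str(outdir / "tss_ratio_counts.json")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir
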