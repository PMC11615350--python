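"""Synthetic ChIP-seq experiment generator with planted ground truth.

Emulates the structure of the study's deposited ChIP-seq design: two
genotypes (WT, KO) x triplicate IP samples x one shared input per
genotype, with planted "WT_enriched" / "KO_enriched" / "unchanged" binding
sites (a configurable fraction of each enriched class genotype-exclusive)
and genotype-differential signal downstream of TSSs.  Everything the
pipeline consumes — annotation BEDs, per-replicate narrowPeak calls,
per-sample bedGraph tracks — can be emitted as files, and a truth table
records what was planted so recovery is scoreable.

Noise model: replicate-level multiplicative lognormal noise on the planted
fold change (coverage ratios behave multiplicatively); per-replicate peak
dropout with a fixed probability; small uniform jitter on peak edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .consensus import ReplicatePeakSet
from .coverage import CoverageTrack
from .genome import Gene, GenomeAnnotation, GenomicInterval, annotate_cgi
from .io import (
    NarrowPeakRecord,
    write_bed,
    write_bedgraph,
    write_chrom_sizes,
    write_gene_table,
    write_narrowpeak,
)

GENOTYPES = ("WT", "KO")

WT_ENRICHED = "WT_enriched"
KO_ENRICHED = "KO_enriched"
UNCHANGED = "unchanged"


def generate_annotation(
    n_genes: int = 200,
    n_chroms: int = 2,
    chrom_len: int = 3_000_000,
    cgi_fraction: float = 0.6,
    seed: int = 0,
    gene_len_range: Tuple[int, int] = (2_000, 10_000),
) -> GenomeAnnotation:
    """Non-overlapping genes with random strands and planted CGI flags.

    Genes are laid out in per-chromosome slots with a 3 kb inset from slot
    boundaries, so neighbouring TSSs are always > 6 kb apart and a CGI
    placed at one TSS can never fall inside another gene's promoter window
    — ``has_cgi`` therefore recovers the planted flag exactly.  Exactly
    ``round(n_genes * cgi_fraction)`` genes receive a CGI.  Deterministic
    given *seed*.
    """
    if n_genes <= 0 or n_chroms <= 0 or chrom_len <= 0:
        raise ValueError("n_genes, n_chroms and chrom_len must be positive")
    if not (0.0 <= cgi_fraction <= 1.0):
        raise ValueError("cgi_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    margin = 3_000
    per_chrom = [n_genes // n_chroms] * n_chroms
    for i in range(n_genes % n_chroms):
        per_chrom[i] += 1
    chrom_sizes = {f"chr{i + 1}": chrom_len for i in range(n_chroms)}
    genes: List[Gene] = []
    gidx = 0
    for ci, (chrom, count) in enumerate(zip(sorted(chrom_sizes), per_chrom)):
        if count == 0:
            continue
        slot = chrom_len // count
        if slot < gene_len_range[1] + 2 * margin:
            raise ValueError(
                f"{count} genes do not fit on a {chrom_len} bp chromosome"
            )
        for s in range(count):
            length = int(rng.integers(gene_len_range[0], gene_len_range[1] + 1))
            lo = s * slot + margin
            hi = (s + 1) * slot - margin - length
            start = int(rng.integers(lo, hi + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            gidx += 1
            genes.append(
                Gene(
                    f"gene{gidx:04d}",
                    GenomicInterval(chrom, start, start + length, strand),
                )
            )
    n_cgi = int(round(n_genes * cgi_fraction))
    cgi_gene_idx = rng.permutation(n_genes)[:n_cgi]
    cgis = []
    for i in sorted(cgi_gene_idx):
        g = genes[i]
        cgis.append(
            GenomicInterval(g.chrom, max(0, g.tss - 300), g.tss + 500)
        )
    genes = annotate_cgi(genes, cgis)
    return GenomeAnnotation(genes=genes, cgis=cgis, chrom_sizes=chrom_sizes)


@dataclass
class TruthParams:
    """Counts and separation margins for planted binding-site classes.

    Enriched sites sit ``enriched_margin`` x beyond BOTH classification
    thresholds; unchanged sites sit at ``unchanged_margin`` x the fc
    threshold (ratio exactly 1), keeping classes separable at the default
    noise level.
    """

    n_wt_enriched: int = 150
    n_ko_enriched: int = 150
    n_unchanged: int = 300
    exclusive_fraction: float = 0.25
    enriched_margin: float = 1.5
    unchanged_margin: float = 0.75
    fc_threshold: float = 3.0
    ratio_log2_threshold: float = 0.23
    site_width: int = 600

    def __post_init__(self) -> None:
        if self.enriched_margin <= 1.0:
            raise ValueError("enriched_margin must exceed 1 for separable classes")
        if not (0.0 < self.unchanged_margin < 1.0):
            raise ValueError("unchanged_margin must lie in (0, 1)")
        if not (0.0 <= self.exclusive_fraction <= 1.0):
            raise ValueError("exclusive_fraction must lie in [0, 1]")

    @property
    def n_sites(self) -> int:
        return self.n_wt_enriched + self.n_ko_enriched + self.n_unchanged


@dataclass
class SyntheticExperiment:
    """In-memory synthetic ChIP experiment plus its truth table."""

    annotation: GenomeAnnotation
    target: str
    replicate_peaks: Dict[str, List[ReplicatePeakSet]]  # genotype -> replicates
    ip_tracks: Dict[str, List[CoverageTrack]]
    input_tracks: Dict[str, CoverageTrack]
    truth: pd.DataFrame  # site_id, chrom, start, end, label, fc_wt, fc_ko, present_in, n_reps_wt, n_reps_ko

    def write(self, outdir) -> Dict[str, object]:
        """Emit the standard files the pipeline consumes; returns paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: Dict[str, object] = {}
        write_chrom_sizes(self.annotation.chrom_sizes, outdir / "genome.chrom.sizes")
        write_gene_table(self.annotation, outdir / "genes.bed")
        write_bed(self.annotation.cgis, outdir / "cgis.bed")
        paths["chrom_sizes"] = str(outdir / "genome.chrom.sizes")
        paths["genes"] = str(outdir / "genes.bed")
        paths["cgis"] = str(outdir / "cgis.bed")
        peaks: Dict[str, List[str]] = {}
        tracks: Dict[str, List[str]] = {}
        inputs: Dict[str, str] = {}
        for gt in GENOTYPES:
            peaks[gt] = []
            tracks[gt] = []
            for i, rep in enumerate(self.replicate_peaks[gt], start=1):
                p = outdir / f"{self.target}_{gt}_rep{i}.narrowPeak"
                write_narrowpeak(rep.peaks, p)
                peaks[gt].append(str(p))
                t = outdir / f"{self.target}_{gt}_rep{i}.bedgraph"
                write_bedgraph(self.ip_tracks[gt][i - 1], t)
                tracks[gt].append(str(t))
            ip = outdir / f"input_{gt}.bedgraph"
            write_bedgraph(self.input_tracks[gt], ip)
            inputs[gt] = str(ip)
        paths["peaks"] = peaks
        paths["ip_tracks"] = tracks
        paths["input_tracks"] = inputs
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        paths["truth"] = str(outdir / "truth.tsv")
        return paths


def _place_sites(
    annotation: GenomeAnnotation, n_sites: int, width: int, rng: np.random.Generator
) -> List[GenomicInterval]:
    """Non-overlapping site intervals in genome-wide 2 kb slots."""
    slot = 2_000
    slots: List[Tuple[str, int]] = []
    for chrom in sorted(annotation.chrom_sizes):
        size = annotation.chrom_sizes[chrom]
        slots.extend((chrom, s) for s in range(0, size - slot, slot))
    if n_sites > len(slots):
        raise ValueError(f"{n_sites} sites do not fit in {len(slots)} slots")
    chosen = rng.choice(len(slots), size=n_sites, replace=False)
    sites = []
    for idx in sorted(chosen):
        chrom, s = slots[idx]
        jmax = slot - width - 2 * 100  # 100 bp inset keeps jittered peaks in-slot
        start = s + 100 + int(rng.integers(0, jmax + 1))
        sites.append(GenomicInterval(chrom, start, start + width))
    return sites


def generate_experiment(
    annotation: GenomeAnnotation,
    truth_params: Optional[TruthParams] = None,
    depth: float = 10.0,
    noise_sd: float = 0.2,
    dropout_rate: float = 0.1,
    seed: int = 42,
    n_replicates: int = 3,
    jitter_bp: int = 25,
    target: str = "KDM2A",
) -> SyntheticExperiment:
    """Generate replicate peak calls, coverage tracks, and a truth table.

    Input coverage is a flat background of *depth* per genotype; IP
    coverage equals the background everywhere except over planted sites,
    where it is background x planted fc x lognormal(sd=noise_sd) per
    replicate.  Peak calls are the site intervals (edges jittered up to
    ``jitter_bp``), each independently dropped from a replicate with
    probability ``dropout_rate``; genotype-exclusive sites appear only in
    their genotype.  All randomness derives from *seed*.
    """
    tp = truth_params or TruthParams()
    if not (0.0 <= dropout_rate <= 1.0):
        raise ValueError("dropout_rate must lie in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    sites = _place_sites(annotation, tp.n_sites, tp.site_width, rng)
    order = rng.permutation(tp.n_sites)

    fc_hi = tp.fc_threshold * tp.enriched_margin
    # the weaker genotype of an enriched common site sits enriched_margin x
    # below the ratio cutoff relative to the stronger one
    fc_lo = fc_hi / (2.0 ** tp.ratio_log2_threshold * tp.enriched_margin)
    fc_flat = tp.fc_threshold * tp.unchanged_margin

    labels = (
        [WT_ENRICHED] * tp.n_wt_enriched
        + [KO_ENRICHED] * tp.n_ko_enriched
        + [UNCHANGED] * tp.n_unchanged
    )
    n_excl_wt = int(round(tp.n_wt_enriched * tp.exclusive_fraction))
    n_excl_ko = int(round(tp.n_ko_enriched * tp.exclusive_fraction))

    records = []
    for rank, site_idx in enumerate(order):
        label = labels[rank]
        if label == WT_ENRICHED:
            exclusive = rank < n_excl_wt
            present = ("WT",) if exclusive else ("WT", "KO")
            fc_wt, fc_ko = fc_hi, (math.nan if exclusive else fc_lo)
        elif label == KO_ENRICHED:
            exclusive = rank - tp.n_wt_enriched < n_excl_ko
            present = ("KO",) if exclusive else ("WT", "KO")
            fc_wt, fc_ko = (math.nan if exclusive else fc_lo), fc_hi
        else:
            present = ("WT", "KO")
            fc_wt = fc_ko = fc_flat
        iv = sites[site_idx]
        records.append(
            {
                "site_id": f"site{site_idx + 1:04d}",
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "label": label,
                "fc_wt": fc_wt,
                "fc_ko": fc_ko,
                "present_in": ",".join(present),
            }
        )
    truth = pd.DataFrame(records).sort_values(["chrom", "start"]).reset_index(drop=True)

    replicate_peaks: Dict[str, List[ReplicatePeakSet]] = {}
    ip_tracks: Dict[str, List[CoverageTrack]] = {}
    input_tracks: Dict[str, CoverageTrack] = {}
    n_reps_retained = {gt: np.zeros(len(truth), dtype=int) for gt in GENOTYPES}

    for gt in GENOTYPES:
        input_tracks[gt] = CoverageTrack.from_records(
            [
                (chrom, 0, size, depth)
                for chrom, size in sorted(annotation.chrom_sizes.items())
            ],
            annotation.chrom_sizes,
        )
        replicate_peaks[gt] = []
        ip_tracks[gt] = []
        for rep in range(1, n_replicates + 1):
            rep_id = f"{gt}_rep{rep}"
            cov_records: List[Tuple[str, int, int, float]] = []
            pos = {chrom: 0 for chrom in annotation.chrom_sizes}
            peak_records: List[NarrowPeakRecord] = []
            for row_i, row in truth.iterrows():
                present = row["present_in"].split(",")
                if gt not in present:
                    continue
                fc = row["fc_wt"] if gt == "WT" else row["fc_ko"]
                mult = (
                    float(np.exp(rng.normal(0.0, noise_sd))) if noise_sd > 0 else 1.0
                )
                chrom, start, end = row["chrom"], int(row["start"]), int(row["end"])
                if start > pos[chrom]:
                    cov_records.append((chrom, pos[chrom], start, depth))
                cov_records.append((chrom, start, end, depth * fc * mult))
                pos[chrom] = end
                if rng.random() >= dropout_rate:
                    j1 = int(rng.integers(-jitter_bp, jitter_bp + 1)) if jitter_bp else 0
                    j2 = int(rng.integers(-jitter_bp, jitter_bp + 1)) if jitter_bp else 0
                    n_reps_retained[gt][row_i] += 1
                    peak_records.append(
                        NarrowPeakRecord(
                            interval=GenomicInterval(
                                chrom, max(0, start + j1), end + j2
                            ),
                            name=f"{row['site_id']}_{rep_id}",
                            score=0,
                            signal_value=depth * fc * mult,
                            summit_offset=(end + j2 - max(0, start + j1)) // 2,
                        )
                    )
            for chrom, size in sorted(annotation.chrom_sizes.items()):
                if pos[chrom] < size:
                    cov_records.append((chrom, pos[chrom], size, depth))
            cov_records.sort()
            ip_tracks[gt].append(
                CoverageTrack.from_records(cov_records, annotation.chrom_sizes)
            )
            replicate_peaks[gt].append(
                ReplicatePeakSet(
                    genotype=gt, target=target, replicate_id=rep_id,
                    peaks=sorted(
                        peak_records, key=lambda p: (p.interval.chrom, p.interval.start)
                    ),
                )
            )

    truth["n_reps_wt"] = n_reps_retained["WT"]
    truth["n_reps_ko"] = n_reps_retained["KO"]
    return SyntheticExperiment(
        annotation=annotation,
        target=target,
        replicate_peaks=replicate_peaks,
        ip_tracks=ip_tracks,
        input_tracks=input_tracks,
        truth=truth,
    )


@dataclass
class SyntheticTssExperiment:
    """Tracks with genotype-differential TSS-downstream signal."""

    annotation: GenomeAnnotation
    wt_tracks: List[CoverageTrack]
    ko_tracks: List[CoverageTrack]
    truth: pd.DataFrame  # gene_id, cgi, planted_ratio

    def write(self, outdir) -> Dict[str, object]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: Dict[str, object] = {"wt": [], "ko": []}
        for name, tracks in (("wt", self.wt_tracks), ("ko", self.ko_tracks)):
            for i, t in enumerate(tracks, start=1):
                p = outdir / f"H3K36me2_{name.upper()}_rep{i}.bedgraph"
                write_bedgraph(t, p)
                paths[name].append(str(p))
        self.truth.to_csv(outdir / "tss_truth.tsv", sep="\t", index=False)
        paths["truth"] = str(outdir / "tss_truth.tsv")
        return paths


def generate_tss_experiment(
    annotation: GenomeAnnotation,
    frac_lower: float = 0.724,
    window_bp: int = 2500,
    depth: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 42,
    n_replicates: int = 3,
) -> SyntheticTssExperiment:
    """Plant per-gene KO/WT downstream-signal ratios.

    A ``frac_lower`` fraction of genes get a planted KO/WT ratio drawn
    uniformly from (0.4, 0.9) (KO below WT, emulating mark loss); the rest
    from (1.1, 2.0).  Coverage inside each gene's strand-aware downstream
    window ``[tss, tss + window_bp)`` is set to a per-gene WT level (and
    that level x ratio in KO), with background *depth* elsewhere; at
    ``noise_sd = 0`` the measured per-gene ratio equals the planted one
    exactly.
    """
    if not (0.0 <= frac_lower <= 1.0):
        raise ValueError("frac_lower must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = annotation.genes
    n = len(genes)
    n_lower = int(round(n * frac_lower))
    lower_idx = set(rng.permutation(n)[:n_lower].tolist())
    rows = []
    windows = []  # (chrom, start, end, wt_level, ratio)
    for i, g in enumerate(genes):
        ratio = (
            float(rng.uniform(0.4, 0.9))
            if i in lower_idx
            else float(rng.uniform(1.1, 2.0))
        )
        wt_level = depth * float(rng.uniform(1.5, 4.0))
        if g.strand == "+":
            start, end = g.tss, g.tss + window_bp
        else:
            start, end = g.tss - window_bp + 1, g.tss + 1
        size = annotation.chrom_sizes[g.chrom]
        start, end = max(0, start), min(size, end)
        windows.append((g.chrom, start, end, wt_level, ratio))
        rows.append(
            {"gene_id": g.gene_id, "cgi": g.has_cgi, "planted_ratio": ratio}
        )
    windows.sort()

    def build(level_of) -> List[CoverageTrack]:
        tracks = []
        for _ in range(n_replicates):
            recs: List[Tuple[str, int, int, float]] = []
            pos = {chrom: 0 for chrom in annotation.chrom_sizes}
            for chrom, start, end, wt_level, ratio in windows:
                mult = (
                    float(np.exp(rng.normal(0.0, noise_sd))) if noise_sd > 0 else 1.0
                )
                if start > pos[chrom]:
                    recs.append((chrom, pos[chrom], start, depth))
                recs.append((chrom, start, end, level_of(wt_level, ratio) * mult))
                pos[chrom] = end
            for chrom, size in sorted(annotation.chrom_sizes.items()):
                if pos[chrom] < size:
                    recs.append((chrom, pos[chrom], size, depth))
            recs.sort()
            tracks.append(CoverageTrack.from_records(recs, annotation.chrom_sizes))
        return tracks

    wt_tracks = build(lambda w, r: w)
    ko_tracks = build(lambda w, r: w * r)
    return SyntheticTssExperiment(
        annotation=annotation,
        wt_tracks=wt_tracks,
        ko_tracks=ko_tracks,
        truth=pd.DataFrame(rows),
    )
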