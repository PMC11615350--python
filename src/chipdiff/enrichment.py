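"""Fold-change-over-input enrichment calls and genomic distribution.

The enrichment statistic per peak is the average fold change (fc): the
mean over IP replicates of mean peak coverage divided by input coverage
over the same span, with both tracks on the same per-million library
scale.  A two-threshold rule labels peaks:

* common peaks (bound in both genotypes): genotype-enriched iff that
  genotype's fc > ``fc_threshold`` AND |log2(fc_wt/fc_ko)| >
  ``ratio_log2_threshold`` with the matching sign (strict inequalities);
* genotype-exclusive peaks: enriched iff that genotype's fc >
  ``fc_threshold``.

Everything failing the rule stays "unclassified".
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .consensus import PeakPartition
from .coverage import CoverageTrack
from .genome import GenomeAnnotation, GenomicInterval

WT_ENRICHED = "WT_enriched"
KO_ENRICHED = "KO_enriched"
UNCLASSIFIED = "unclassified"
LABELS = (WT_ENRICHED, KO_ENRICHED, UNCLASSIFIED)
ORIGINS = ("common", "wt_only", "ko_only")

CATEGORIES = ("promoter_tss", "gene_body", "intergenic")


@dataclass(frozen=True)
class EnrichmentCall:
    peak: GenomicInterval
    origin: str  # common | wt_only | ko_only
    fc_wt: Optional[float]
    fc_ko: Optional[float]
    log2_ratio: Optional[float]
    label: str
    gene_id: Optional[str] = None
    tss_distance: Optional[int] = None
    region_category: Optional[str] = None


@dataclass
class EnrichmentResult:
    calls: List[EnrichmentCall]

    @property
    def summary(self) -> Dict[str, Dict[str, int]]:
        """Counts per label, per origin, and the label x origin table."""
        by_label = Counter(c.label for c in self.calls)
        by_origin = Counter(c.origin for c in self.calls)
        cross = Counter((c.origin, c.label) for c in self.calls)
        return {
            "by_label": {k: by_label.get(k, 0) for k in LABELS},
            "by_origin": {k: by_origin.get(k, 0) for k in ORIGINS},
            "by_origin_label": {
                f"{o}:{l}": cross.get((o, l), 0) for o in ORIGINS for l in LABELS
            },
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.calls:
            rows.append(
                {
                    "chrom": c.peak.chrom,
                    "start": c.peak.start,
                    "end": c.peak.end,
                    "origin": c.origin,
                    "fc_wt": c.fc_wt,
                    "fc_ko": c.fc_ko,
                    "log2_ratio": c.log2_ratio,
                    "label": c.label,
                    "gene_id": c.gene_id,
                    "tss_distance": c.tss_distance,
                    "region_category": c.region_category,
                }
            )
        return pd.DataFrame(rows)


def peak_fold_change(
    peak: GenomicInterval,
    ip_tracks: Sequence[CoverageTrack],
    input_track: CoverageTrack,
    epsilon: float = 0.25,
    mode: str = "mean_of_ratios",
) -> float:
    """Average fold change of IP over input across replicates on one peak.

    ``mean_of_ratios`` (default): mean over replicates of
    (mean IP coverage) / max(mean input coverage, epsilon).
    ``ratio_of_means``: replicate-averaged IP coverage divided by the
    floored input coverage.  The epsilon floor (default 0.25, a quarter of
    one scaled read) guards peaks with zero input coverage.
    """
    if not ip_tracks:
        raise ValueError("need at least one IP track")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    denom = max(input_track.mean(peak.chrom, peak.start, peak.end), epsilon)
    ip_means = [t.mean(peak.chrom, peak.start, peak.end) for t in ip_tracks]
    if mode == "mean_of_ratios":
        return float(sum(m / denom for m in ip_means) / len(ip_means))
    if mode == "ratio_of_means":
        return float((sum(ip_means) / len(ip_means)) / denom)
    raise ValueError(f"unknown fc mode {mode!r}")


def classify_enrichment(
    partition: PeakPartition,
    fc_common: Sequence[Tuple[float, float]],
    fc_wt_only: Sequence[float],
    fc_ko_only: Sequence[float],
    fc_threshold: float = 3.0,
    ratio_log2_threshold: float = 0.23,
) -> EnrichmentResult:
    """Apply the two-threshold genotype-enrichment rule to a partition.

    ``fc_common[i]`` is ``(fc_wt, fc_ko)`` over the union span of the i-th
    matched pair; exclusive peaks carry a single fc.  All inequalities are
    strict: fc exactly at the threshold, or a log2 ratio exactly at the
    cutoff, stays unclassified.
    """
    if len(fc_common) != len(partition.common):
        raise ValueError("fc missing for some common peaks")
    if len(fc_wt_only) != len(partition.wt_only) or len(fc_ko_only) != len(
        partition.ko_only
    ):
        raise ValueError("fc missing for some exclusive peaks")
    calls: List[EnrichmentCall] = []
    for i, (fc_wt, fc_ko) in enumerate(fc_common):
        if fc_wt is None or fc_ko is None:
            raise ValueError(f"missing fc for common peak {i}")
        span = partition.common_span(i)
        ratio = math.log2(fc_wt / fc_ko) if fc_wt > 0 and fc_ko > 0 else math.nan
        if fc_wt > fc_threshold and ratio > ratio_log2_threshold:
            label = WT_ENRICHED
        elif fc_ko > fc_threshold and -ratio > ratio_log2_threshold:
            label = KO_ENRICHED
        else:
            label = UNCLASSIFIED
        calls.append(
            EnrichmentCall(
                peak=span, origin="common", fc_wt=fc_wt, fc_ko=fc_ko,
                log2_ratio=ratio, label=label,
            )
        )
    for pk, fc in zip(partition.wt_only, fc_wt_only):
        label = WT_ENRICHED if fc > fc_threshold else UNCLASSIFIED
        calls.append(
            EnrichmentCall(
                peak=pk.interval, origin="wt_only", fc_wt=fc, fc_ko=None,
                log2_ratio=None, label=label,
            )
        )
    for pk, fc in zip(partition.ko_only, fc_ko_only):
        label = KO_ENRICHED if fc > fc_threshold else UNCLASSIFIED
        calls.append(
            EnrichmentCall(
                peak=pk.interval, origin="ko_only", fc_wt=None, fc_ko=fc,
                log2_ratio=None, label=label,
            )
        )
    return EnrichmentResult(calls=calls)


def annotate_calls(
    result: EnrichmentResult,
    annotation: GenomeAnnotation,
    promoter_halfwidth: int = 2000,
) -> EnrichmentResult:
    """Attach nearest-TSS gene, signed distance, and genomic category."""
    out = []
    for c in result.calls:
        pos = c.peak.midpoint
        try:
            gene_id, dist = annotation.nearest_tss(c.peak.chrom, pos)
        except LookupError:
            gene_id, dist = None, None
        category = categorize_position(
            c.peak.chrom, pos, annotation, promoter_halfwidth
        )
        out.append(
            EnrichmentCall(
                peak=c.peak, origin=c.origin, fc_wt=c.fc_wt, fc_ko=c.fc_ko,
                log2_ratio=c.log2_ratio, label=c.label, gene_id=gene_id,
                tss_distance=dist, region_category=category,
            )
        )
    return EnrichmentResult(calls=out)


def rollup_genes(result: EnrichmentResult) -> pd.DataFrame:
    """Per-label distinct-gene and peak counts (genes <= peaks).

    Returns one row per label present among annotated calls, with the set
    size of distinct nearest-TSS genes and the peak tally.
    """
    rows = []
    for label in LABELS:
        calls = [c for c in result.calls if c.label == label and c.gene_id]
        genes = {c.gene_id for c in calls}
        rows.append({"label": label, "n_genes": len(genes), "n_peaks": len(calls)})
    return pd.DataFrame(rows)


def categorize_position(
    chrom: str,
    pos: int,
    annotation: GenomeAnnotation,
    promoter_halfwidth: int = 2000,
) -> str:
    """Assign one genomic category with priority promoter > gene body > intergenic.

    Promoter/TSS means within +/- promoter_halfwidth of any TSS (the
    published definition, TSS +/- 2 kb); gene body means inside any gene
    interval; everything else is intergenic.
    """
    genes = annotation.genes_on(chrom)
    for g in genes:
        if abs(pos - g.tss) <= promoter_halfwidth:
            return "promoter_tss"
    for g in genes:
        if g.interval.start <= pos < g.interval.end:
            return "gene_body"
    return "intergenic"


def _anchor(pk) -> Tuple[str, int]:
    """Summit of a peak-like object, or the interval midpoint."""
    if hasattr(pk, "summit"):
        return pk.interval.chrom, pk.summit
    iv = pk.interval if hasattr(pk, "interval") else pk
    return iv.chrom, iv.midpoint


def category_counts(
    peaks: Iterable["object"],
    annotation: GenomeAnnotation,
    promoter_halfwidth: int = 2000,
) -> Dict[str, int]:
    """Integer peak counts per genomic category (summit or midpoint)."""
    counts: Counter = Counter()
    for pk in peaks:
        chrom, pos = _anchor(pk)
        counts[categorize_position(chrom, pos, annotation, promoter_halfwidth)] += 1
    return {cat: counts.get(cat, 0) for cat in CATEGORIES}


def genomic_distribution(
    peak_sets: Dict[str, Iterable["object"]],
    annotation: GenomeAnnotation,
    promoter_halfwidth: int = 2000,
) -> pd.DataFrame:
    """Category fractions per sample plus their across-sample average.

    ``peak_sets`` maps a sample name to narrowPeak records (summit used,
    midpoint when absent).  Fractions per sample sum to 1; the "average"
    row is the plain mean of the per-sample fractions, mirroring how
    replicate pie charts are reported.
    """
    rows = {}
    for name, peaks in peak_sets.items():
        counts = Counter()
        total = 0
        for pk in peaks:
            chrom, pos = _anchor(pk)
            counts[categorize_position(chrom, pos, annotation, promoter_halfwidth)] += 1
            total += 1
        rows[name] = {
            cat: (counts.get(cat, 0) / total if total else 0.0) for cat in CATEGORIES
        }
    df = pd.DataFrame(rows).T.reindex(columns=list(CATEGORIES))
    if len(df):
        df.loc["average"] = df.mean(axis=0)
    return df
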