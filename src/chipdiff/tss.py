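"""TSS-anchored signal quantification.

Per-gene mean coverage in a strand-aware window downstream of the TSS
(default 2.5 kb), genotype KO/WT ratio counts over a gene universe, and
metagene matrices (reference-point and scale-regions modes) with
column-mean profiles, in the style of deepTools computeMatrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .genome import Gene, GenomeAnnotation


def tss_window_signal(
    track: CoverageTrack,
    annotation: GenomeAnnotation,
    window_bp: int = 2500,
    cgi_only: bool = True,
) -> Dict[str, float]:
    """Mean coverage in the downstream TSS window, per gene.

    The window is strand-aware: ``[tss, tss + window_bp)`` on the + strand
    and ``(tss - window_bp, tss]`` (i.e. ``[tss - window_bp + 1, tss + 1)``)
    on the - strand, clipped at chromosome ends; the mean is taken over the
    clipped span.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    out: Dict[str, float] = {}
    for g in annotation.genes:
        if cgi_only and not g.has_cgi:
            continue
        if g.strand == "+":
            start, end = g.tss, g.tss + window_bp
        else:
            start, end = g.tss - window_bp + 1, g.tss + 1
        out[g.gene_id] = track.mean_clipped(g.chrom, start, end)
    return out


@dataclass
class RatioCounts:
    table: pd.DataFrame  # gene_id, cgi, mean_wt, mean_ko, ratio
    n_lower: int  # ratio < 1 (KO below WT)
    n_higher: int  # ratio > 1
    n_other: int  # ratio exactly 1 or undefined (mean_wt == 0)


def genotype_ratio_counts(
    wt_means: Dict[str, float],
    ko_means: Dict[str, float],
    annotation: Optional[GenomeAnnotation] = None,
) -> RatioCounts:
    """KO/WT per-gene ratio table and lower/higher counts.

    Per-genotype means are expected to be replicate averages already; the
    ratio is mean_ko / mean_wt.  Genes with zero WT mean have an undefined
    ratio and are excluded from both directional counts (reported in
    ``n_other`` together with exact ties).
    """
    if set(wt_means) != set(ko_means):
        raise ValueError("gene universes differ between WT and KO means")
    cgi_flags = (
        {g.gene_id: g.has_cgi for g in annotation.genes} if annotation else {}
    )
    rows = []
    n_lower = n_higher = n_other = 0
    for gene_id in sorted(wt_means):
        mw, mk = wt_means[gene_id], ko_means[gene_id]
        ratio = mk / mw if mw > 0 else np.nan
        if np.isnan(ratio) or ratio == 1.0:
            n_other += 1
        elif ratio < 1.0:
            n_lower += 1
        else:
            n_higher += 1
        rows.append(
            {
                "gene_id": gene_id,
                "cgi": cgi_flags.get(gene_id),
                "mean_wt": mw,
                "mean_ko": mk,
                "ratio": ratio,
            }
        )
    return RatioCounts(pd.DataFrame(rows), n_lower, n_higher, n_other)


@dataclass
class MetageneMatrix:
    """Regions x bins matrix of mean scaled coverage, plus its profile."""

    matrix: np.ndarray
    region_ids: List[str]
    bin_size: int
    flank: int
    mode: str  # reference_point | scale_regions
    body_bins: int = 0

    @property
    def profile(self) -> np.ndarray:
        """Column means over regions (the metagene curve)."""
        return self.matrix.mean(axis=0) if len(self.matrix) else self.matrix.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        if self.mode == "reference_point":
            cols = np.arange(-self.flank, self.flank, self.bin_size)
        else:
            cols = np.arange(self.matrix.shape[1])
        return pd.DataFrame(self.matrix, index=self.region_ids, columns=cols)


def metagene_matrix(
    track: CoverageTrack,
    regions: Sequence[Gene],
    mode: str = "reference_point",
    flank_bp: int = 10000,
    bin_size: int = 50,
    body_bins: int = 100,
) -> MetageneMatrix:
    """Binned coverage matrix over strand-oriented regions.

    ``reference_point`` mode anchors at each region's TSS and tiles
    ``[tss - flank_bp, tss + flank_bp)``; rows of minus-strand regions are
    reversed so downstream always reads rightward.  ``scale_regions`` mode
    rescales each gene body onto ``body_bins`` bins, flanked by unscaled
    ``flank_bp`` windows on either side.  Bases beyond chromosome ends
    contribute 0.
    """
    if mode not in ("reference_point", "scale_regions"):
        raise ValueError(f"unknown metagene mode {mode!r}")
    if bin_size <= 0 or (2 * flank_bp) % bin_size:
        raise ValueError(f"bin_size {bin_size} must divide the window span")
    flank_bins = flank_bp // bin_size
    rows = []
    ids = []
    for g in regions:
        if mode == "reference_point":
            row = track.binned(
                g.chrom, g.tss - flank_bp, g.tss + flank_bp, bin_size
            )
        else:
            up = track.binned(
                g.chrom, g.interval.start - flank_bp, g.interval.start, bin_size
            )
            down = track.binned(
                g.chrom, g.interval.end, g.interval.end + flank_bp, bin_size
            )
            body = _rescaled_body(track, g, body_bins)
            row = np.concatenate([up, body, down])
        if g.strand == "-":
            row = row[::-1]
        rows.append(row)
        ids.append(g.gene_id)
    mat = np.vstack(rows) if rows else np.zeros((0, 2 * flank_bins))
    return MetageneMatrix(
        matrix=mat, region_ids=ids, bin_size=bin_size, flank=flank_bp,
        mode=mode, body_bins=body_bins if mode == "scale_regions" else 0,
    )


def _rescaled_body(track: CoverageTrack, g: Gene, body_bins: int) -> np.ndarray:
    """Gene body averaged onto a fixed bin count (variable bp per bin)."""
    start, end = g.interval.start, g.interval.end
    edges = np.linspace(start, end, body_bins + 1)
    st = track._steps(g.chrom)
    size = track.chrom_sizes[g.chrom]
    vals = np.empty(body_bins)
    for i in range(body_bins):
        a, b = edges[i], edges[i + 1]
        a_c, b_c = max(0.0, a), min(float(size), b)
        integ = st._point(int(round(b_c))) - st._point(int(round(a_c))) if b_c > a_c else 0.0
        vals[i] = track.scale_factor * integ / (b - a)
    return vals
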