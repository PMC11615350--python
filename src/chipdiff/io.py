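"""Readers and writers for the text formats the pipeline touches.

Supported on-disk formats: BED3/BED6, ENCODE narrowPeak (6-10 columns),
bedGraph, 2-column chrom.sizes, and YAML pipeline configuration.  All
positions are kept 0-based half-open, as in the files themselves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Union

import yaml

from .coverage import CoverageTrack
from .genome import (
    CGI_PROMOTER_HALFWIDTH,
    Gene,
    GenomeAnnotation,
    GenomicInterval,
    annotate_cgi,
)

logger = logging.getLogger("chipdiff")

PathLike = Union[str, Path]


@dataclass(frozen=True)
class NarrowPeakRecord:
    """One MACS2-style narrowPeak line.

    Optional columns absent from shorter BED files are filled with the
    format's missing-value conventions (-1, ".", 0).
    """

    interval: GenomicInterval
    name: str = "."
    score: int = 0
    signal_value: float = -1.0
    p_neglog10: float = -1.0
    q_neglog10: float = -1.0
    summit_offset: int = -1

    def __post_init__(self) -> None:
        width = len(self.interval)
        if self.summit_offset != -1 and not (0 <= self.summit_offset < width):
            raise ValueError(
                f"summit offset {self.summit_offset} outside peak of width {width}"
            )

    @property
    def summit(self) -> int:
        """Absolute summit position; midpoint when no summit was called."""
        if self.summit_offset == -1:
            return self.interval.midpoint
        return self.interval.start + self.summit_offset


class FormatError(ValueError):
    """Malformed line in a genomics text file; message names the line."""


def _parse_lines(path: PathLike):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_narrowpeak(path: PathLike) -> List[NarrowPeakRecord]:
    """Read a narrowPeak/BED file into records, preserving file order."""
    records = []
    for lineno, fields in _parse_lines(path):
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: fewer than 3 columns")
        try:
            chrom = fields[0]
            start, end = int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(f"start {start} >= end {end}")
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            rec = NarrowPeakRecord(
                interval=GenomicInterval(chrom, start, end, strand),
                name=fields[3] if len(fields) > 3 else ".",
                score=int(float(fields[4])) if len(fields) > 4 and fields[4] != "." else 0,
                signal_value=float(fields[6]) if len(fields) > 6 else -1.0,
                p_neglog10=float(fields[7]) if len(fields) > 7 else -1.0,
                q_neglog10=float(fields[8]) if len(fields) > 8 else -1.0,
                summit_offset=int(fields[9]) if len(fields) > 9 else -1,
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        records.append(rec)
    return records


def write_narrowpeak(records: Iterable[NarrowPeakRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        for r in records:
            iv = r.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.name}\t{r.score}\t{iv.strand}"
                f"\t{r.signal_value:g}\t{r.p_neglog10:g}\t{r.q_neglog10:g}"
                f"\t{r.summit_offset}\n"
            )


def read_chrom_sizes(path: PathLike) -> Dict[str, int]:
    sizes: Dict[str, int] = {}
    for lineno, fields in _parse_lines(path):
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: need chrom and size")
        chrom, size = fields[0], int(fields[1])
        if size <= 0 or chrom in sizes:
            raise FormatError(f"{path}:{lineno}: bad or duplicate chromosome")
        sizes[chrom] = size
    return sizes


def read_bedgraph(
    path: PathLike,
    chrom_sizes: Dict[str, int],
    scale_factor: float = 1.0,
) -> CoverageTrack:
    """Read a bedGraph into a :class:`CoverageTrack`.

    Records must be non-overlapping per chromosome and within chromosome
    bounds; uncovered positions get value 0.
    """
    recs = []
    for lineno, fields in _parse_lines(path):
        if len(fields) < 4:
            raise FormatError(f"{path}:{lineno}: need 4 bedGraph columns")
        try:
            recs.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    try:
        return CoverageTrack.from_records(recs, chrom_sizes, scale_factor)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_bedgraph(track: CoverageTrack, path: PathLike, omit_zero: bool = True) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.records():
            if omit_zero and value == 0.0:
                continue
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def read_bed_intervals(path: PathLike) -> List[GenomicInterval]:
    """Read BED3+ intervals (strand taken from column 6 when present)."""
    out = []
    for lineno, fields in _parse_lines(path):
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: fewer than 3 columns")
        try:
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def read_gene_table(
    path_genes: PathLike,
    path_cgi: Optional[PathLike],
    chrom_sizes_path_or_map: Union[PathLike, Dict[str, int]],
    cgi_halfwidth: int = CGI_PROMOTER_HALFWIDTH,
) -> GenomeAnnotation:
    """Load genes (BED6, name = gene_id, strand required) and CGIs (BED3+).

    ``has_cgi`` is computed with the TSS +/- *cgi_halfwidth* overlap rule.
    """
    if isinstance(chrom_sizes_path_or_map, dict):
        chrom_sizes = dict(chrom_sizes_path_or_map)
    else:
        chrom_sizes = read_chrom_sizes(chrom_sizes_path_or_map)
    genes: List[Gene] = []
    seen = set()
    for lineno, fields in _parse_lines(path_genes):
        if len(fields) < 6:
            raise FormatError(f"{path_genes}:{lineno}: genes need 6 BED columns")
        if fields[5] not in ("+", "-"):
            raise FormatError(f"{path_genes}:{lineno}: missing or invalid strand")
        gene_id = fields[3]
        if gene_id in seen:
            raise FormatError(f"{path_genes}:{lineno}: duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        try:
            iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]), fields[5])
        except ValueError as exc:
            raise FormatError(f"{path_genes}:{lineno}: {exc}") from exc
        genes.append(Gene(gene_id, iv))
    cgis = read_bed_intervals(path_cgi) if path_cgi else []
    genes = annotate_cgi(genes, cgis, halfwidth=cgi_halfwidth)
    return GenomeAnnotation(genes=genes, cgis=cgis, chrom_sizes=chrom_sizes)


def write_gene_table(annotation: GenomeAnnotation, genes_path: PathLike) -> None:
    with open(genes_path, "w") as fh:
        for g in annotation.genes:
            iv = g.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.gene_id}\t0\t{iv.strand}\n")


def write_chrom_sizes(chrom_sizes: Dict[str, int], path: PathLike) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(chrom_sizes):
            fh.write(f"{chrom}\t{chrom_sizes[chrom]}\n")


def log_filter_step(stage: str, before: int, after: int, what: str) -> None:
    """Structured log line for an audit of every filtering step."""
    logger.info(
        "%s: %s: %d -> %d (removed %d)", stage, what, before, after, before - after
    )
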