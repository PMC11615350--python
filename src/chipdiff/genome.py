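"""Coordinate types and interval arithmetic.

All coordinates are 0-based half-open ``[start, end)`` throughout the
package, matching BED/narrowPeak/bedGraph conventions; conversion (if any)
happens only at file boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

STRANDS = ("+", "-", ".")

#: Half-width of the promoter window around a TSS (bp); a gene "has a CGI"
#: when a CpG-island interval overlaps [tss - CGI_PROMOTER_HALFWIDTH,
#: tss + CGI_PROMOTER_HALFWIDTH).
CGI_PROMOTER_HALFWIDTH = 2000


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff *a* and *b* share at least one base (same chromosome)."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of shared bases (0 if disjoint or on different chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


@dataclass(frozen=True)
class Gene:
    """A gene with a strand-resolved transcription start site.

    ``tss`` is ``interval.start`` on the + strand and ``interval.end - 1``
    on the - strand (the last covered base, so it lies inside the interval).
    ``has_cgi`` is true iff a CpG island overlaps the TSS +/- 2 kb window.
    """

    gene_id: str
    interval: GenomicInterval
    has_cgi: bool = False

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def tss(self) -> int:
        if self.interval.strand == "+":
            return self.interval.start
        return self.interval.end - 1

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand


class NoNeighborError(LookupError):
    """Raised when a nearest-TSS query hits a chromosome with no genes."""


@dataclass
class GenomeAnnotation:
    """Genes, CpG islands and chromosome sizes.

    Builds per-chromosome sorted TSS arrays once so nearest-TSS queries are
    O(log n).
    """

    genes: List[Gene]
    cgis: List[GenomicInterval] = field(default_factory=list)
    chrom_sizes: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
        if self.chrom_sizes:
            for g in self.genes:
                size = self.chrom_sizes.get(g.chrom)
                if size is None or g.interval.end > size:
                    raise ValueError(
                        f"gene {g.gene_id} exceeds chrom bounds on {g.chrom}"
                    )
            for c in self.cgis:
                size = self.chrom_sizes.get(c.chrom)
                if size is None or c.end > size:
                    raise ValueError(f"CGI {c} exceeds chrom bounds")
        self._tss_index: Dict[str, Tuple[np.ndarray, List[Gene]]] = {}
        by_chrom: Dict[str, List[Gene]] = {}
        for g in self.genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for chrom, genes in by_chrom.items():
            # sort by (tss, gene_id) so equidistant ties resolve to the
            # lexicographically smallest gene_id deterministically
            genes.sort(key=lambda g: (g.tss, g.gene_id))
            self._tss_index[chrom] = (
                np.array([g.tss for g in genes], dtype=np.int64),
                genes,
            )

    @property
    def gene_ids(self) -> List[str]:
        return [g.gene_id for g in self.genes]

    def genes_by_id(self) -> Dict[str, Gene]:
        return {g.gene_id: g for g in self.genes}

    def genes_on(self, chrom: str) -> List[Gene]:
        entry = self._tss_index.get(chrom)
        return entry[1] if entry else []

    def nearest_tss(self, chrom: str, pos: int) -> Tuple[str, int]:
        """Nearest-TSS gene and signed distance for a genomic position.

        Returns ``(gene_id, signed_distance)`` where positive distance means
        downstream of the TSS in the gene's orientation: ``pos - tss`` on the
        + strand, ``tss - pos`` on the - strand.  Ties on absolute distance
        go to the lexicographically smallest gene_id.

        Raises :class:`NoNeighborError` if the chromosome has no genes.
        """
        entry = self._tss_index.get(chrom)
        if entry is None:
            raise NoNeighborError(f"no gene on chromosome {chrom!r}")
        tss_arr, genes = entry
        i = int(np.searchsorted(tss_arr, pos))
        # candidates: every gene tied with the nearest TSS on either side,
        # so the gene_id tie-break sees all equidistant genes
        best: Optional[Gene] = None
        best_dist = None
        candidates: List[Gene] = []
        if i > 0:
            d_left = pos - int(tss_arr[i - 1])
            j = i - 1
            while j >= 0 and pos - int(tss_arr[j]) == d_left:
                candidates.append(genes[j])
                j -= 1
        if i < len(genes):
            d_right = int(tss_arr[i]) - pos
            j = i
            while j < len(genes) and int(tss_arr[j]) - pos == d_right:
                candidates.append(genes[j])
                j += 1
        for g in candidates:
            d = abs(pos - g.tss)
            if best is None or d < best_dist or (d == best_dist and g.gene_id < best.gene_id):
                best, best_dist = g, d
        assert best is not None
        signed = pos - best.tss if best.strand == "+" else best.tss - pos
        return best.gene_id, signed


def annotate_cgi(
    genes: Iterable[Gene],
    cgis: Iterable[GenomicInterval],
    halfwidth: int = CGI_PROMOTER_HALFWIDTH,
) -> List[Gene]:
    """Recompute ``has_cgi`` for genes: CGI overlap with TSS +/- *halfwidth*.

    The promoter window is clipped at 0 on the left; overlap means >= 1
    shared base, half-open semantics.
    """
    cgi_by_chrom: Dict[str, List[GenomicInterval]] = {}
    for c in cgis:
        cgi_by_chrom.setdefault(c.chrom, []).append(c)
    for lst in cgi_by_chrom.values():
        lst.sort(key=lambda c: c.start)
    out = []
    for g in genes:
        win_start = max(0, g.tss - halfwidth)
        win_end = g.tss + halfwidth
        flag = any(
            c.start < win_end and win_start < c.end
            for c in cgi_by_chrom.get(g.chrom, [])
        )
        out.append(Gene(g.gene_id, g.interval, has_cgi=flag))
    return out
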