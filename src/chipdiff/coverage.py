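"""Stepwise per-chromosome coverage tracks.

A :class:`CoverageTrack` is the in-memory form of a bedGraph: per
chromosome, a step function over ``[0, chrom_len)`` with value 0 wherever
no record covers the position.  Each chromosome keeps breakpoint and
cumulative-integral arrays so interval means are O(log n) lookups.

A multiplicative ``scale_factor`` (e.g. reads-per-million normalization)
is applied at query time, so the raw step values stay auditable.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Tuple

import numpy as np


class _ChromSteps:
    """Step function on one chromosome: breakpoints, values, integral."""

    __slots__ = ("bp", "values", "cum")

    def __init__(self, bp: np.ndarray, values: np.ndarray):
        # bp has len(values) + 1 entries; values[i] holds on [bp[i], bp[i+1])
        self.bp = bp
        self.values = values
        self.cum = np.concatenate(([0.0], np.cumsum(values * np.diff(bp))))

    def integral(self, start: int, end: int) -> float:
        """Integral of the step function over [start, end)."""
        return self._point(end) - self._point(start)

    def _point(self, x: int) -> float:
        i = int(np.searchsorted(self.bp, x, side="right")) - 1
        i = max(0, min(i, len(self.values) - 1))
        return float(self.cum[i] + (x - self.bp[i]) * self.values[i])


class CoverageTrack:
    """Genome-wide stepwise signal with a library-size scale factor."""

    def __init__(
        self,
        chrom_sizes: Dict[str, int],
        scale_factor: float = 1.0,
    ):
        self.chrom_sizes = dict(chrom_sizes)
        self.scale_factor = float(scale_factor)
        self._chroms: Dict[str, _ChromSteps] = {}

    @classmethod
    def from_records(
        cls,
        records: Iterable[Tuple[str, int, int, float]],
        chrom_sizes: Dict[str, int],
        scale_factor: float = 1.0,
    ) -> "CoverageTrack":
        """Build from (chrom, start, end, value) records.

        Records per chromosome must be non-overlapping; gaps become 0.
        """
        track = cls(chrom_sizes, scale_factor)
        by_chrom: Dict[str, List[Tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            if chrom not in chrom_sizes:
                raise ValueError(f"unknown chromosome {chrom!r}")
            if not (0 <= start < end <= chrom_sizes[chrom]):
                raise ValueError(
                    f"record {chrom}:{start}-{end} outside chromosome bounds"
                )
            if not np.isfinite(value):
                raise ValueError(f"non-finite value at {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((start, end, value))
        for chrom, recs in by_chrom.items():
            recs.sort()
            size = chrom_sizes[chrom]
            bp: List[int] = [0]
            vals: List[float] = []
            pos = 0
            for start, end, value in recs:
                if start < pos:
                    raise ValueError(
                        f"overlapping bedGraph records on {chrom} at {start}"
                    )
                if start > pos:
                    vals.append(0.0)
                    bp.append(start)
                vals.append(value)
                bp.append(end)
                pos = end
            if pos < size:
                vals.append(0.0)
                bp.append(size)
            track._chroms[chrom] = _ChromSteps(
                np.asarray(bp, dtype=np.int64), np.asarray(vals, dtype=np.float64)
            )
        return track

    def _steps(self, chrom: str) -> _ChromSteps:
        st = self._chroms.get(chrom)
        if st is None:
            if chrom not in self.chrom_sizes:
                raise ValueError(f"unknown chromosome {chrom!r}")
            size = self.chrom_sizes[chrom]
            st = _ChromSteps(
                np.array([0, size], dtype=np.int64), np.zeros(1, dtype=np.float64)
            )
            self._chroms[chrom] = st
        return st

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Mean scaled coverage over [start, end); errors outside bounds."""
        size = self.chrom_sizes.get(chrom)
        if size is None:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if not (0 <= start < end <= size):
            raise ValueError(
                f"query {chrom}:{start}-{end} outside chromosome bounds [0, {size})"
            )
        st = self._steps(chrom)
        return self.scale_factor * st.integral(start, end) / (end - start)

    def mean_clipped(self, chrom: str, start: int, end: int) -> float:
        """Mean over the part of [start, end) inside the chromosome.

        Positions outside the chromosome contribute value 0 and are excluded
        from the denominator; returns 0.0 if the window misses entirely.
        """
        size = self.chrom_sizes.get(chrom)
        if size is None:
            raise ValueError(f"unknown chromosome {chrom!r}")
        s, e = max(0, start), min(size, end)
        if s >= e:
            return 0.0
        return self.mean(chrom, s, e)

    def binned(self, chrom: str, start: int, end: int, bin_size: int) -> np.ndarray:
        """Per-bin means tiling [start, end); out-of-chromosome bases count 0.

        The span must be a multiple of *bin_size*.  Bins overhanging the
        chromosome average the covered part against zeros for the rest, so
        the result is the mean of the zero-padded signal over each bin.
        """
        span = end - start
        if bin_size <= 0 or span % bin_size:
            raise ValueError(f"bin_size {bin_size} must divide span {span}")
        size = self.chrom_sizes[chrom]
        st = self._steps(chrom)
        edges = np.arange(start, end + 1, bin_size, dtype=np.int64)
        clipped = np.clip(edges, 0, size)
        idx = np.clip(
            np.searchsorted(st.bp, clipped, side="right") - 1, 0, len(st.values) - 1
        )
        pts = st.cum[idx] + (clipped - st.bp[idx]) * st.values[idx]
        return self.scale_factor * np.diff(pts) / bin_size

    def total(self) -> float:
        """Total scaled signal: sum over steps of value x length."""
        return self.scale_factor * sum(
            float(st.cum[-1]) for st in self._chroms.values()
        )

    def scaled_per_million(self, total_reads: float) -> "CoverageTrack":
        """Copy of this track rescaled so *total_reads* maps to 1 million."""
        if total_reads <= 0:
            raise ValueError("total_reads must be positive")
        out = CoverageTrack(self.chrom_sizes, self.scale_factor * 1e6 / total_reads)
        out._chroms = self._chroms
        return out

    def records(self) -> List[Tuple[str, int, int, float]]:
        """Scaled (chrom, start, end, value) steps, zero runs included."""
        out = []
        for chrom in sorted(self._chroms):
            st = self._chroms[chrom]
            for i, v in enumerate(st.values):
                out.append(
                    (chrom, int(st.bp[i]), int(st.bp[i + 1]), self.scale_factor * float(v))
                )
        return out
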