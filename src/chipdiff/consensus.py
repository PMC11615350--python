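"""Replicate consensus peaks and genotype partition.

The consensus rule follows the replicate-reproducibility convention:
overlapping peaks across replicates of one condition are merged into union
intervals, and a merged interval is kept only when peaks from at least
``min_reps`` distinct replicates contribute to it (peaks seen in a single
replicate are discarded with the default ``min_reps=2``).

The genotype partition splits consensus peaks into pairs present in both
genotypes ("common") and genotype-exclusive sets, with one-to-one greedy
matching by overlap length so the common count is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .genome import GenomicInterval, overlap_length
from .io import NarrowPeakRecord, log_filter_step


@dataclass
class ReplicatePeakSet:
    """Peak calls from one IP replicate of one genotype and target."""

    genotype: str
    target: str
    replicate_id: str
    peaks: List[NarrowPeakRecord]


@dataclass(frozen=True)
class ConsensusPeak:
    """A merged interval supported by >= min_reps replicates."""

    interval: GenomicInterval
    support_count: int
    members: Tuple[Tuple[str, Tuple[str, ...]], ...]  # replicate_id -> peak names

    @property
    def member_map(self) -> Dict[str, Tuple[str, ...]]:
        return dict(self.members)


@dataclass
class ConsensusPeakSet:
    genotype: str
    target: str
    peaks: List[ConsensusPeak]

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class PeakPartition:
    """Common (paired) and genotype-exclusive consensus peaks.

    Invariant: |WT consensus| = |common| + |wt_only| and symmetrically for
    KO, because the matching is one-to-one.
    """

    target: str
    common: List[Tuple[ConsensusPeak, ConsensusPeak]]  # (wt, ko) pairs
    wt_only: List[ConsensusPeak]
    ko_only: List[ConsensusPeak]

    def common_span(self, i: int) -> GenomicInterval:
        """Union interval of the i-th matched pair (shared fc span)."""
        wt, ko = self.common[i]
        return GenomicInterval(
            wt.interval.chrom,
            min(wt.interval.start, ko.interval.start),
            max(wt.interval.end, ko.interval.end),
        )


def consensus_peaks(
    replicates: Sequence[ReplicatePeakSet], min_reps: int = 2
) -> ConsensusPeakSet:
    """Merge replicate peak calls into a consensus set.

    Overlapping peaks (>= 1 shared base, union-find by coordinate sweep)
    are merged into one union interval; the merged interval survives iff
    it contains peaks from at least ``min_reps`` distinct replicates.
    """
    if not replicates:
        raise ValueError("need at least one replicate peak set")
    genotypes = {r.genotype for r in replicates}
    targets = {r.target for r in replicates}
    if len(genotypes) != 1 or len(targets) != 1:
        raise ValueError(
            f"mixed replicate sets: genotypes={sorted(genotypes)}, targets={sorted(targets)}"
        )
    if min_reps < 1 or min_reps > len(replicates):
        raise ValueError(
            f"min_reps={min_reps} outside [1, {len(replicates)} replicates]"
        )

    # coordinate sweep per chromosome over all replicate peaks
    tagged: List[Tuple[str, int, int, str, str]] = []  # chrom,start,end,rep,name
    for rep in replicates:
        for pk in rep.peaks:
            iv = pk.interval
            tagged.append((iv.chrom, iv.start, iv.end, rep.replicate_id, pk.name))
    tagged.sort()

    merged: List[ConsensusPeak] = []
    n_clusters = 0
    cluster: List[Tuple[str, int, int, str, str]] = []

    def flush() -> None:
        nonlocal n_clusters
        if not cluster:
            return
        n_clusters += 1
        chrom = cluster[0][0]
        start = min(c[1] for c in cluster)
        end = max(c[2] for c in cluster)
        by_rep: Dict[str, List[str]] = {}
        for _, _, _, rep_id, name in cluster:
            by_rep.setdefault(rep_id, []).append(name)
        if len(by_rep) >= min_reps:
            merged.append(
                ConsensusPeak(
                    interval=GenomicInterval(chrom, start, end),
                    support_count=len(by_rep),
                    members=tuple(
                        (rid, tuple(sorted(names)))
                        for rid, names in sorted(by_rep.items())
                    ),
                )
            )
        cluster.clear()

    cur_chrom: Optional[str] = None
    cur_end = -1
    for item in tagged:
        chrom, start, end = item[0], item[1], item[2]
        if chrom != cur_chrom or start >= cur_end:
            flush()
            cur_chrom, cur_end = chrom, end
        else:
            cur_end = max(cur_end, end)
        cluster.append(item)
    flush()

    gt, tgt = genotypes.pop(), targets.pop()
    log_filter_step(
        "consensus", n_clusters, len(merged),
        f"{gt}/{tgt} merged clusters supported by >= {min_reps} replicates",
    )
    return ConsensusPeakSet(genotype=gt, target=tgt, peaks=merged)


def partition_by_genotype(
    wt: ConsensusPeakSet, ko: ConsensusPeakSet
) -> PeakPartition:
    """Split WT/KO consensus peaks into common pairs and exclusive sets.

    Candidate (wt, ko) pairs with >= 1 bp overlap are matched greedily by
    descending overlap length (ties: leftmost KO interval, then leftmost
    WT), one-to-one.  Overlapping peaks left unmatched after greedy pairing
    fall into the exclusive sets, keeping the partition counts exact.
    """
    if wt.target != ko.target:
        raise ValueError(f"target mismatch: {wt.target!r} vs {ko.target!r}")

    ko_by_chrom: Dict[str, List[Tuple[int, ConsensusPeak]]] = {}
    for j, kp in enumerate(ko.peaks):
        ko_by_chrom.setdefault(kp.interval.chrom, []).append((j, kp))
    for lst in ko_by_chrom.values():
        lst.sort(key=lambda t: t[1].interval.start)

    candidates: List[Tuple[int, int, int, int, int, int]] = []
    # (-overlap, ko.start, ko.end, wt.start, wt_idx, ko_idx)
    for i, wp in enumerate(wt.peaks):
        wiv = wp.interval
        for j, kp in ko_by_chrom.get(wiv.chrom, []):
            ov = overlap_length(wiv, kp.interval)
            if ov > 0:
                candidates.append(
                    (-ov, kp.interval.start, kp.interval.end, wiv.start, i, j)
                )
    candidates.sort()

    matched_wt: Dict[int, int] = {}
    matched_ko: Dict[int, int] = {}
    for neg_ov, _, _, _, i, j in candidates:
        if i not in matched_wt and j not in matched_ko:
            matched_wt[i] = j
            matched_ko[j] = i

    common = [
        (wt.peaks[i], ko.peaks[j])
        for i, j in sorted(matched_wt.items())
    ]
    wt_only = [p for i, p in enumerate(wt.peaks) if i not in matched_wt]
    ko_only = [p for j, p in enumerate(ko.peaks) if j not in matched_ko]
    log_filter_step(
        "partition", len(wt.peaks) + len(ko.peaks),
        len(common), f"{wt.target} common pairs from WT+KO consensus peaks",
    )
    return PeakPartition(
        target=wt.target, common=common, wt_only=wt_only, ko_only=ko_only
    )
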