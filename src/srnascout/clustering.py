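"""Merge overlapping alignments into read clusters; minimum-read filter.

Two alignments belong to the same cluster iff they are connected by a chain
of pairwise-overlapping alignments (>= 1 shared base in half-open
arithmetic, same chromosome, and same strand when strand-aware merging is
on). Bookended alignments ([0,20) and [20,40)) do not merge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Tuple

from srnascout.alignments import AlignedRead, GenomicInterval


@dataclass
class ReadCluster:
    """A maximal set of chain-overlapping alignments: one candidate locus.

    The interval spans all member alignments unless an explicit boundary is
    supplied (the boundary optimizer pins refined spans that may be tighter
    than the member footprint).
    """

    cluster_id: str
    members: List[AlignedRead]
    interval: GenomicInterval = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ReadCluster requires at least one member")
        if self.interval is None:
            self.interval = span_of(self.members)

    @property
    def n_total(self) -> int:
        return len(self.members)

    @property
    def n_unique(self) -> int:
        return sum(1 for r in self.members if r.multiplicity == "unique")

    @property
    def n_multi(self) -> int:
        return sum(1 for r in self.members if r.multiplicity == "multi")

    @property
    def read_ids(self) -> set:
        return {r.read_id for r in self.members}


def span_of(members: Iterable[AlignedRead]) -> GenomicInterval:
    members = list(members)
    chrom = members[0].interval.chrom
    strand = members[0].interval.strand
    if any(r.interval.chrom != chrom for r in members):
        raise ValueError("cluster members span multiple chromosomes")
    if len({r.interval.strand for r in members}) > 1:
        strand = "."
    return GenomicInterval(
        chrom=chrom,
        start=min(r.interval.start for r in members),
        end=max(r.interval.end for r in members),
        strand=strand,
    )


def _sort_key(read: AlignedRead, strand_aware: bool) -> Tuple:
    iv = read.interval
    if strand_aware:
        return (iv.chrom, iv.strand, iv.start, iv.end, read.read_id)
    return (iv.chrom, iv.start, iv.end, read.read_id)


def build_clusters(
    reads: Iterable[AlignedRead],
    strand_aware: bool = True,
    id_prefix: str = "cluster",
) -> List[ReadCluster]:
    """Single sweep over position-sorted alignments, emitting a cluster at
    every gap. Chain-overlap connectivity makes the result independent of
    input order (the input is sorted internally)."""
    reads = sorted(reads, key=lambda r: _sort_key(r, strand_aware))
    clusters: List[ReadCluster] = []
    current: List[AlignedRead] = []
    current_end = -1

    def flush() -> None:
        if current:
            clusters.append(
                ReadCluster(
                    cluster_id=f"{id_prefix}_{len(clusters) + 1:05d}",
                    members=list(current),
                )
            )

    prev_group = None
    for read in reads:
        iv = read.interval
        group = (iv.chrom, iv.strand) if strand_aware else (iv.chrom,)
        if group != prev_group or iv.start >= current_end:
            flush()
            current = []
            current_end = -1
            prev_group = group
        current.append(read)
        current_end = max(current_end, iv.end)
    flush()
    return clusters


def filter_min_reads(
    clusters: List[ReadCluster], number_reads: int = 5
) -> Tuple[List[ReadCluster], List[ReadCluster]]:
    """Partition clusters into (kept, dropped) by the minimum-read filter.

    A cluster is dropped iff it contains fewer than ``number_reads``
    alignments; equality is kept. Dropped clusters are retained for the
    rejected-output report.
    """
    if number_reads < 1:
        raise ValueError("number_reads must be >= 1")
    kept = [c for c in clusters if c.n_total >= number_reads]
    dropped = [c for c in clusters if c.n_total < number_reads]
    return kept, dropped


def clusters_to_bed(clusters: Iterable[ReadCluster]) -> str:
    """BED6 dump (chrom, start, end, cluster_id, n_total, strand) for
    debugging intermediate cluster sets."""
    lines = []
    for c in clusters:
        iv = c.interval
        lines.append(
            f"{iv.chrom}\t{iv.start}\t{iv.end}\t{c.cluster_id}\t{c.n_total}\t{iv.strand}"
        )
    return "\n".join(lines) + ("\n" if lines else "")
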