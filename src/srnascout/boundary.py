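"""Coverage-weighted boundary optimization of read clusters.

Each read in a cluster gets a weight: the mean per-base coverage over the
bases it spans,

    Rw = (sum_i cov(p_i)) / n

where ``cov(p)`` is the cluster's read depth at base ``p`` and ``n`` the
read length. Reads that merely bridge two dense stacks, or trail off a
locus edge, have low weight.

The optimizer provisionally removes the lowest-weight fraction of reads
(``percent_cur``), splits the remainder (H1) into sub-clusters at
zero-coverage transitions, and cuts the original cluster (H0) into sections
at the midpoints of the gaps between H1 sub-clusters. Per candidate
sub-cluster, the mean coverage of the H0 section and the H1 sub-cluster
are compared: the refined H1 boundaries are accepted only when the
coverage ratio clears ``1 + cutoff``; otherwise the H0 section's reads and
boundaries are retained, and consecutive retained sections are merged
back into a single cluster.

The printed orientation of the acceptance ratio, W(H0)/W(H1), favours
retaining H0 in the typical case (removing reads can only lower
coverage). Both orientations are supported through ``ratio_orientation``;
``inverted`` (W(H1)/W(H0)) is the splitting-effective direction.
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from srnascout.alignments import AlignedRead, GenomicInterval
from srnascout.clustering import ReadCluster, span_of

logger = logging.getLogger(__name__)


@dataclass
class CoverageProfile:
    """Per-base read depth over an interval."""

    origin: GenomicInterval
    depths: np.ndarray

    def mean_over(self, start: int, end: int) -> float:
        """Mean depth over absolute coordinates [start, end)."""
        lo = max(start, self.origin.start) - self.origin.start
        hi = min(end, self.origin.end) - self.origin.start
        if hi <= lo:
            return 0.0
        return float(self.depths[lo:hi].mean())


@dataclass(frozen=True)
class WeightedRead:
    read: AlignedRead
    weight: float
    rank: int


@dataclass(frozen=True)
class BoundaryParams:
    """Knobs of the boundary optimizer.

    percent_cur : fraction of lowest-weight reads provisionally removed
                  (default 0.3). The removal count is
                  floor(percent_cur * n_total).
    cutoff      : acceptance margin; refined boundaries are accepted when
                  the coverage ratio exceeds 1 + cutoff (default 0.3).
    ratio_orientation : "as_written" compares W(H0)/W(H1); "inverted"
                  compares W(H1)/W(H0).
    """

    percent_cur: float = 0.3
    cutoff: float = 0.3
    ratio_orientation: str = "as_written"

    def __post_init__(self) -> None:
        if not (0 <= self.percent_cur < 1):
            raise ValueError("percent_cur must be in [0, 1)")
        if self.cutoff < 0:
            raise ValueError("cutoff must be >= 0")
        if self.ratio_orientation not in ("as_written", "inverted"):
            raise ValueError(
                f"unknown ratio_orientation {self.ratio_orientation!r}"
            )


def coverage_profile(
    members: Iterable[AlignedRead], origin: GenomicInterval
) -> CoverageProfile:
    depths = np.zeros(origin.length, dtype=np.int64)
    for read in members:
        iv = read.interval
        if iv.start < origin.start or iv.end > origin.end:
            raise ValueError(
                f"read {read.read_id} extends outside cluster interval"
            )
        depths[iv.start - origin.start : iv.end - origin.start] += 1
    return CoverageProfile(origin=origin, depths=depths)


def compute_read_weights(cluster: ReadCluster) -> List[WeightedRead]:
    """Weight every member read by its mean coverage, ascending.

    Ties are broken by (start, end, read_id) so the removal set used by
    the optimizer is a deterministic prefix.
    """
    profile = coverage_profile(cluster.members, cluster.interval)
    origin = cluster.interval.start
    items = []
    for read in cluster.members:
        iv = read.interval
        total = int(profile.depths[iv.start - origin : iv.end - origin].sum())
        items.append((total / iv.length, read))
    items.sort(key=lambda t: (t[0], t[1].interval.start, t[1].interval.end, t[1].read_id))
    return [
        WeightedRead(read=read, weight=w, rank=i)
        for i, (w, read) in enumerate(items)
    ]


def _coverage_runs(depths: np.ndarray, offset: int) -> List[Tuple[int, int]]:
    """Maximal runs of positive depth, in absolute coordinates."""
    covered = (depths > 0).astype(np.int8)
    edges = np.diff(np.concatenate([[0], covered, [0]]))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return [(int(s) + offset, int(e) + offset) for s, e in zip(starts, ends)]


def optimize_boundaries(
    cluster: ReadCluster, params: Optional[BoundaryParams] = None
) -> List[ReadCluster]:
    """Refine a cluster's boundaries; may split it into sub-clusters.

    Runs a single pass of the remove/split/compare procedure described in
    the module docstring. Returned sub-clusters have recomputed intervals
    and counts; accepted sub-clusters keep the refined H1 span even after
    low-weight reads overlapping it are re-attached (so expression counts
    reflect all supporting reads), while removed reads overlapping no
    accepted sub-cluster are dropped.
    """
    if params is None:
        params = BoundaryParams()

    n_remove = math.floor(params.percent_cur * cluster.n_total)
    weighted = compute_read_weights(cluster)
    removed = [w.read for w in weighted[:n_remove]]
    h1_reads = [w.read for w in weighted[n_remove:]]
    if not h1_reads:
        return [cluster]

    origin = cluster.interval
    h0_profile = coverage_profile(cluster.members, origin)
    h1_profile = coverage_profile(h1_reads, origin)
    runs = _coverage_runs(h1_profile.depths, origin.start)
    if not runs:
        return [cluster]

    # H0 section boundaries: cluster ends plus the midpoint of each gap
    # between consecutive H1 sub-clusters (one section per run).
    cuts = [origin.start]
    for (_, prev_end), (next_start, _) in zip(runs, runs[1:]):
        cuts.append((prev_end + next_start) // 2)
    cuts.append(origin.end)

    accepted: List[bool] = []
    for i, (run_start, run_end) in enumerate(runs):
        w_h1 = h1_profile.mean_over(run_start, run_end)
        w_h0 = h0_profile.mean_over(cuts[i], cuts[i + 1])
        if params.ratio_orientation == "as_written":
            ratio = w_h0 / w_h1 if w_h1 > 0 else math.inf
        else:
            ratio = w_h1 / w_h0 if w_h0 > 0 else math.inf
        ok = ratio > 1 + params.cutoff
        accepted.append(ok)
        logger.debug(
            "cluster %s section %d [%d,%d): W(H0)=%.3f W(H1)=%.3f ratio=%.3f -> %s",
            cluster.cluster_id, i, run_start, run_end, w_h0, w_h1, ratio,
            "accept H1" if ok else "retain H0",
        )

    def section_index(read: AlignedRead) -> int:
        # sections partition [origin.start, origin.end); assign by start
        return min(bisect_right(cuts, read.interval.start) - 1, len(runs) - 1)

    h1_by_section: List[List[AlignedRead]] = [[] for _ in runs]
    for read in h1_reads:
        h1_by_section[section_index(read)].append(read)
    h0_by_section: List[List[AlignedRead]] = [[] for _ in runs]
    for read in cluster.members:
        h0_by_section[section_index(read)].append(read)

    outputs: List[dict] = []
    i = 0
    while i < len(runs):
        if accepted[i]:
            outputs.append(
                {
                    "members": list(h1_by_section[i]),
                    "interval": GenomicInterval(
                        origin.chrom, runs[i][0], runs[i][1], origin.strand
                    ),
                    "accepted": True,
                }
            )
            i += 1
        else:
            members: List[AlignedRead] = []
            lo, hi = cuts[i], cuts[i]
            while i < len(runs) and not accepted[i]:
                members.extend(h0_by_section[i])
                hi = cuts[i + 1]
                i += 1
            if members:
                span = span_of(members)
                outputs.append(
                    {
                        "members": members,
                        "interval": GenomicInterval(
                            origin.chrom,
                            max(span.start, lo),
                            min(span.end, hi),
                            origin.strand,
                        ),
                        "accepted": False,
                    }
                )

    # Re-attach provisionally removed reads whose H0 section was replaced
    # by an accepted sub-cluster; drop those overlapping none.
    accepted_out = [o for o in outputs if o["accepted"]]
    for read in removed:
        if not accepted[section_index(read)]:
            continue  # already retained with its H0 section
        best = None
        best_ov = 0
        for o in accepted_out:
            ov = read.interval.intersection_length(o["interval"])
            if ov > best_ov:
                best, best_ov = o, ov
        if best is not None:
            best["members"].append(read)

    result = []
    for k, o in enumerate(outputs):
        if not o["members"]:
            continue
        result.append(
            ReadCluster(
                cluster_id=f"{cluster.cluster_id}.{k + 1}" if len(outputs) > 1 else cluster.cluster_id,
                members=o["members"],
                interval=o["interval"],
            )
        )
    return result if result else [cluster]
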