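"""SAM/BAM ingestion, CIGAR quality filtering, and read-multiplicity classes.

Alignments are read with :mod:`pysam` and converted to 0-based half-open
coordinates. Reads are grouped into three multiplicity classes by their
genome-wide number of alignments (the hit count):

* ``unique`` - exactly one alignment,
* ``multi``  - 2 up to ``number_hits`` alignments (kept),
* ``repeat`` - more than ``number_hits`` alignments (discarded).

The CIGAR filter admits only alignments whose insertions and deletions are
short (``max_indel_len``) and flanked on both sides by aligned-match runs of
at least ``min_flank_len`` bases. Soft-clipped bases do not count toward
flank length.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Tuple

import pysam

logger = logging.getLogger(__name__)

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

#: CIGAR operations that consume aligned (matched) reference bases and
#: therefore count toward indel flank length.
MATCH_OPS = frozenset("M=X")
INDEL_OPS = frozenset("ID")


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded, 0-based half-open genomic range.

    This is the coordinate currency of every pipeline stage; GTF input
    (1-based inclusive) is converted on load.
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two ranges share at least one base (strand ignored)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class AlignedRead:
    """One alignment of one sequencing read."""

    read_id: str
    interval: GenomicInterval
    cigar: str
    hit_count: int
    multiplicity: str  # "unique" | "multi" | "repeat"

    def __post_init__(self) -> None:
        if self.hit_count < 1:
            raise ValueError("hit_count must be >= 1")
        if self.multiplicity not in ("unique", "multi", "repeat"):
            raise ValueError(f"invalid multiplicity {self.multiplicity!r}")


@dataclass(frozen=True)
class CigarPolicy:
    """Tunable CIGAR quality thresholds.

    max_indel_len : longest admissible insertion or deletion run (bases).
    min_flank_len : shortest aligned-match run required on both sides of
                    every indel (bases).
    """

    max_indel_len: int = 5
    min_flank_len: int = 5

    def __post_init__(self) -> None:
        if self.max_indel_len < 0 or self.min_flank_len < 0:
            raise ValueError("CigarPolicy thresholds must be >= 0")


def parse_cigar(cigar: str) -> List[Tuple[int, str]]:
    """Split a CIGAR string into (length, op) runs, validating syntax."""
    if not cigar or cigar == "*":
        raise ValueError(f"malformed CIGAR: {cigar!r}")
    runs = _CIGAR_RE.findall(cigar)
    if "".join(f"{n}{op}" for n, op in runs) != cigar:
        raise ValueError(f"malformed CIGAR: {cigar!r}")
    return [(int(n), op) for n, op in runs]


def cigar_passes(cigar: str, policy: CigarPolicy) -> bool:
    """True iff every indel run is short enough and properly flanked.

    Each insertion or deletion run must have length <= ``max_indel_len``
    and be immediately flanked on both sides by aligned-match runs (M/=/X)
    of length >= ``min_flank_len``. An indel at either end of the
    alignment, or adjacent to a clip or another indel, fails.
    """
    runs = parse_cigar(cigar)
    for i, (length, op) in enumerate(runs):
        if op not in INDEL_OPS:
            continue
        if length > policy.max_indel_len:
            return False
        if i == 0 or i == len(runs) - 1:
            return False
        left_len, left_op = runs[i - 1]
        right_len, right_op = runs[i + 1]
        if left_op not in MATCH_OPS or left_len < policy.min_flank_len:
            return False
        if right_op not in MATCH_OPS or right_len < policy.min_flank_len:
            return False
    return True


@dataclass
class AlignmentStats:
    """Bookkeeping of the ingestion filters (one entry per drop reason)."""

    total: int = 0
    yielded_unique: int = 0
    yielded_multi: int = 0
    dropped_repeat: int = 0
    dropped_cigar: int = 0
    skipped_unmapped: int = 0
    skipped_no_read_id: int = 0

    def as_dict(self) -> Dict[str, int]:
        return dict(self.__dict__)


def _record_usable(rec: pysam.AlignedSegment) -> bool:
    if rec.is_unmapped or rec.is_qcfail:
        return False
    if rec.reference_id < 0 or rec.reference_start is None:
        return False
    return True


def _collect_hit_counts(
    path: str,
    policy: CigarPolicy,
    count_after_filter: bool,
) -> Dict[str, int]:
    """First pass: genome-wide alignment count per read id.

    The NH tag is trusted when present; otherwise records sharing a read id
    are counted, which requires all alignments of a read to be present in
    the file (e.g. an aligner run in report-all-hits mode).
    """
    counts: Dict[str, int] = {}
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for rec in fh:
            if not _record_usable(rec):
                continue
            name = rec.query_name
            if not name or name == "*":
                continue
            if count_after_filter:
                try:
                    if not cigar_passes(rec.cigarstring or "", policy):
                        continue
                except ValueError:
                    continue
            if rec.has_tag("NH"):
                nh = int(rec.get_tag("NH"))
                counts[name] = max(counts.get(name, 0), nh)
            else:
                counts[name] = counts.get(name, 0) + 1
    return counts


def read_alignments(
    path: str,
    policy: Optional[CigarPolicy] = None,
    number_hits: int = 5,
    count_hits_after_filter: bool = False,
    stats: Optional[AlignmentStats] = None,
) -> Iterator[AlignedRead]:
    """Stream quality-filtered alignments from a SAM/BAM file.

    Parameters
    ----------
    path
        SAM or BAM file. Unmapped, QC-fail, and coordinate-less records
        are skipped.
    policy
        CIGAR thresholds; defaults apply when omitted.
    number_hits
        Reads with more than this many genome-wide alignments are
        classified as ``repeat`` and dropped entirely (default 5).
    count_hits_after_filter
        When True, a read's hit count only includes alignments that pass
        the CIGAR filter; the default counts genome-wide multiplicity
        before filtering.
    stats
        Optional mutable counter object filled in place; drop counts are
        also logged at the end of iteration.

    Yields
    ------
    AlignedRead
        Every CIGAR-passing alignment of every unique or multi-mapped
        read, with ``hit_count`` aggregated across all its alignments.
    """
    if policy is None:
        policy = CigarPolicy()
    if number_hits < 1:
        raise ValueError("number_hits must be >= 1")
    if stats is None:
        stats = AlignmentStats()

    hit_counts = _collect_hit_counts(path, policy, count_hits_after_filter)

    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for rec in fh:
            stats.total += 1
            if not _record_usable(rec):
                stats.skipped_unmapped += 1
                continue
            name = rec.query_name
            if not name or name == "*":
                stats.skipped_no_read_id += 1
                logger.warning("alignment record without read id skipped")
                continue
            cigar = rec.cigarstring or ""
            if not cigar_passes(cigar, policy):
                stats.dropped_cigar += 1
                continue
            hits = hit_counts.get(name, 1)
            if hits > number_hits:
                stats.dropped_repeat += 1
                continue
            multiplicity = "unique" if hits == 1 else "multi"
            if multiplicity == "unique":
                stats.yielded_unique += 1
            else:
                stats.yielded_multi += 1
            yield AlignedRead(
                read_id=name,
                interval=GenomicInterval(
                    chrom=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                ),
                cigar=cigar,
                hit_count=hits,
                multiplicity=multiplicity,
            )
    logger.info(
        "alignments: %d total, %d unique, %d multi kept; dropped %d repeat, "
        "%d cigar; skipped %d unmapped, %d nameless",
        stats.total,
        stats.yielded_unique,
        stats.yielded_multi,
        stats.dropped_repeat,
        stats.dropped_cigar,
        stats.skipped_unmapped,
        stats.skipped_no_read_id,
    )
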