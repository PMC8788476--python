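"""Synthetic small-RNA alignment datasets with a known truth table.

The generator plants loci of the canonical small-RNA length classes on
synthetic contigs (chrT1, chrT2, ...) and simulates reads over them:

* ``mirna_like``  17-25 nt   * ``pirna_like``  20-40 nt
* ``trna_like``   60-90 nt   * ``snorna_like`` 60-150 nt
* ``decoy_coding`` - a multi-exon protein-coding decoy whose transcription
  must be vetoed downstream,
* ``noise``        - scattered low-weight reads.

Read starts and ends are jittered +/-2 nt around the planted boundaries
(the fuzz the boundary optimizer must absorb). Multi-copy loci place
homologous copies at fixed offsets and emit every read once per copy with
the same read id, producing genuine multi-mapped reads. Output can be
written as minimal valid SAM plus truth TSV and matching GTFs, or
consumed in memory as :class:`~srnascout.alignments.AlignedRead` records.

What this emulates - and what it does not: coverage stacking, boundary
fuzz, multi-mapping, and decoy transcription are modelled; base
composition, sequencing error, and expression dispersion of real
libraries are not.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from srnascout.alignments import AlignedRead, GenomicInterval
from srnascout.classify import ClassifiedCluster

LENGTH_CLASSES: Dict[str, Tuple[int, int]] = {
    "mirna_like": (17, 25),
    "pirna_like": (20, 40),
    "trna_like": (60, 90),
    "snorna_like": (60, 150),
}

CLASS_BIOTYPE: Dict[str, str] = {
    "mirna_like": "miRNA",
    "pirna_like": "piRNA",
    "trna_like": "tRNA",
    "snorna_like": "snoRNA",
}

#: genomic spacing between homologous copies of a multi-copy locus
COPY_SPACING = 10_000


@dataclass(frozen=True)
class PlantedLocus:
    locus_id: str
    interval: GenomicInterval
    biotype_class: str
    copies: int = 1
    depth: int = 0
    expected_verdict: str = "annotated"

    def __post_init__(self) -> None:
        if self.copies < 1:
            raise ValueError("copies must be >= 1")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.biotype_class in LENGTH_CLASSES:
            lo, hi = LENGTH_CLASSES[self.biotype_class]
            if not (lo <= self.interval.length <= hi):
                raise ValueError(
                    f"{self.locus_id}: length {self.interval.length} outside "
                    f"{self.biotype_class} range [{lo}, {hi}]"
                )

    def copy_intervals(self) -> List[GenomicInterval]:
        iv = self.interval
        return [
            GenomicInterval(iv.chrom, iv.start + k * COPY_SPACING, iv.end + k * COPY_SPACING, iv.strand)
            for k in range(self.copies)
        ]


@dataclass
class SyntheticDataset:
    alignments: List[AlignedRead]
    truth: List[PlantedLocus]
    seed: int
    reference_names: List[str]

    def contig_lengths(self) -> Dict[str, int]:
        lengths: Dict[str, int] = {name: 1000 for name in self.reference_names}
        for rec in self.alignments:
            iv = rec.interval
            lengths[iv.chrom] = max(lengths.get(iv.chrom, 0), iv.end + 1000)
        for locus in self.truth:
            for iv in locus.copy_intervals():
                lengths[iv.chrom] = max(lengths.get(iv.chrom, 0), iv.end + 1000)
        return lengths

    def write_sam(self, path: str) -> None:
        lengths = self.contig_lengths()
        names = sorted(lengths)
        header = pysam.AlignmentHeader.from_dict(
            {
                "HD": {"VN": "1.6", "SO": "coordinate"},
                "SQ": [{"SN": n, "LN": lengths[n]} for n in names],
            }
        )
        ref_index = {n: i for i, n in enumerate(names)}
        records = sorted(
            self.alignments,
            key=lambda r: (ref_index[r.interval.chrom], r.interval.start, r.read_id),
        )
        seen: set = set()
        with pysam.AlignmentFile(path, "w", header=header) as out:
            for rec in records:
                a = pysam.AlignedSegment(header)
                a.query_name = rec.read_id
                flag = 16 if rec.interval.strand == "-" else 0
                if rec.read_id in seen:
                    flag |= 256  # secondary: an extra hit of a multi-mapped read
                seen.add(rec.read_id)
                a.flag = flag
                a.reference_id = ref_index[rec.interval.chrom]
                a.reference_start = rec.interval.start
                a.mapping_quality = 30 if rec.hit_count == 1 else 1
                a.cigarstring = rec.cigar
                a.query_sequence = "A" * rec.interval.length
                a.set_tag("NH", rec.hit_count)
                out.write(a)

    def write_truth(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(
                "#locus_id\tchrom\tstart\tend\tstrand\tclass\tcopies\tdepth\texpected_verdict\n"
            )
            for t in self.truth:
                iv = t.interval
                fh.write(
                    f"{t.locus_id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t"
                    f"{t.biotype_class}\t{t.copies}\t{t.depth}\t{t.expected_verdict}\n"
                )

    def write_small_rna_gtf(self, path: str) -> None:
        """GTF (1-based inclusive) of the planted small-RNA loci, one
        transcript per homologous copy."""
        with open(path, "w") as fh:
            for t in self.truth:
                if t.biotype_class not in CLASS_BIOTYPE:
                    continue
                biotype = CLASS_BIOTYPE[t.biotype_class]
                for k, iv in enumerate(t.copy_intervals(), start=1):
                    tid = t.locus_id if t.copies == 1 else f"{t.locus_id}_copy{k}"
                    attrs = (
                        f'gene_id "{tid}"; transcript_id "{tid}"; '
                        f'gene_biotype "{biotype}"; gene_name "{tid}";'
                    )
                    fh.write(
                        f"{iv.chrom}\tsynthetic\ttranscript\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
                    )

    def write_host_gtf(self, path: str) -> None:
        """GTF of the protein-coding decoy transcripts (two exons each)."""
        with open(path, "w") as fh:
            for t in self.truth:
                if t.biotype_class != "decoy_coding":
                    continue
                iv = t.interval
                attrs = (
                    f'gene_id "{t.locus_id}"; transcript_id "{t.locus_id}"; '
                    f'gene_biotype "protein_coding"; gene_name "{t.locus_id}";'
                )
                fh.write(
                    f"{iv.chrom}\tsynthetic\ttranscript\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
                )
                for exon in _decoy_exons(iv):
                    fh.write(
                        f"{iv.chrom}\tsynthetic\texon\t{exon.start + 1}\t{exon.end}\t.\t{iv.strand}\t.\t{attrs}\n"
                    )


def _decoy_exons(iv: GenomicInterval) -> List[GenomicInterval]:
    exon_len = max(40, min(120, iv.length // 3))
    return [
        GenomicInterval(iv.chrom, iv.start, iv.start + exon_len, iv.strand),
        GenomicInterval(iv.chrom, iv.end - exon_len, iv.end, iv.strand),
    ]


def _check_placements(loci: Sequence[PlantedLocus]) -> None:
    placed: List[Tuple[str, int, int, str]] = []
    for locus in loci:
        if locus.biotype_class == "noise":
            continue  # noise deliberately straddles junctions
        for iv in locus.copy_intervals():
            placed.append((iv.chrom, iv.start, iv.end, locus.locus_id))
    placed.sort()
    for (c1, s1, e1, id1), (c2, s2, e2, id2) in zip(placed, placed[1:]):
        if c1 == c2 and s2 < e1 and id1 != id2:
            raise ValueError(f"unintended overlap between {id1} and {id2}")


def _jittered(rng: np.random.Generator, iv: GenomicInterval, jitter: int) -> Tuple[int, int]:
    start = iv.start + int(rng.integers(-jitter, jitter + 1))
    end = iv.end + int(rng.integers(-jitter, jitter + 1))
    start = max(0, start)
    if end - start < 15:
        end = start + 15
    return start, end


def generate(
    loci: Sequence[PlantedLocus], seed: int, jitter: int = 2
) -> SyntheticDataset:
    """Simulate alignments for a list of planted loci, deterministically.

    For each locus, ``depth`` reads are drawn with boundaries jittered
    +/-``jitter`` nt; a read of a ``copies``-fold locus is emitted once
    per copy (same read id, hit_count = copies). Decoy-coding loci emit
    reads over their two exons; noise loci scatter short reads across
    their interval. Same seed, same byte-identical output.
    """
    _check_placements(loci)
    rng = np.random.default_rng(seed)
    alignments: List[AlignedRead] = []
    for locus in loci:
        copy_ivs = locus.copy_intervals()
        multiplicity = "unique" if locus.copies == 1 else "multi"
        if locus.biotype_class == "decoy_coding":
            exons = _decoy_exons(locus.interval)
            for i in range(locus.depth):
                exon = exons[i % len(exons)]
                read_len = int(rng.integers(20, min(41, exon.length + 1)))
                start = exon.start + int(
                    rng.integers(0, exon.length - read_len + 1)
                )
                alignments.append(
                    AlignedRead(
                        read_id=f"{locus.locus_id}_r{i:05d}",
                        interval=GenomicInterval(
                            exon.chrom, start, start + read_len, exon.strand
                        ),
                        cigar=f"{read_len}M",
                        hit_count=1,
                        multiplicity="unique",
                    )
                )
        elif locus.biotype_class == "noise":
            iv = locus.interval
            for i in range(locus.depth):
                read_len = int(rng.integers(20, 41))
                start = iv.start + int(
                    rng.integers(0, max(1, iv.length - read_len))
                )
                alignments.append(
                    AlignedRead(
                        read_id=f"{locus.locus_id}_r{i:05d}",
                        interval=GenomicInterval(
                            iv.chrom, start, start + read_len, iv.strand
                        ),
                        cigar=f"{read_len}M",
                        hit_count=1,
                        multiplicity="unique",
                    )
                )
        else:
            for i in range(locus.depth):
                start0, end0 = _jittered(rng, locus.interval, jitter)
                offset_s = start0 - locus.interval.start
                offset_e = end0 - locus.interval.end
                read_id = f"{locus.locus_id}_r{i:05d}"
                for iv in copy_ivs:
                    s, e = iv.start + offset_s, iv.end + offset_e
                    alignments.append(
                        AlignedRead(
                            read_id=read_id,
                            interval=GenomicInterval(iv.chrom, s, e, iv.strand),
                            cigar=f"{e - s}M",
                            hit_count=locus.copies,
                            multiplicity=multiplicity,
                        )
                    )
    reference_names = sorted({a.interval.chrom for a in alignments})
    return SyntheticDataset(
        alignments=alignments,
        truth=list(loci),
        seed=seed,
        reference_names=reference_names,
    )


# ---------------------------------------------------------------------------
# study scenarios


def default_scenario(seed: int = 0) -> SyntheticDataset:
    """The standard end-to-end study set: 20 planted single-copy loci (5
    per length class, depths 150-350), 2 multi-exon protein-coding decoys,
    and low-depth noise clusters, ~5,000 alignments in total."""
    depths = [350, 300, 250, 200, 150]
    class_lengths = {
        # lengths keep a 2-nt jitter margin inside each class range
        "mirna_like": [21, 21, 21, 21, 21],
        "pirna_like": [24, 28, 30, 33, 36],
        "trna_like": [64, 70, 75, 80, 86],
        "snorna_like": [64, 85, 105, 125, 146],
    }
    loci: List[PlantedLocus] = []
    for c, (cls, lengths) in enumerate(class_lengths.items()):
        chrom = f"chrT{c + 1}"
        pos = 1_000
        for i, (length, depth) in enumerate(zip(lengths, depths)):
            loci.append(
                PlantedLocus(
                    locus_id=f"{cls}_{i + 1:02d}",
                    interval=GenomicInterval(chrom, pos, pos + length, "+"),
                    biotype_class=cls,
                    depth=depth,
                )
            )
            pos += 5_000
    for i in range(2):
        pos = 1_000 + i * 5_000
        loci.append(
            PlantedLocus(
                locus_id=f"decoy_{i + 1:02d}",
                interval=GenomicInterval("chrT5", pos, pos + 600, "+"),
                biotype_class="decoy_coding",
                depth=150,
                expected_verdict="rejected",
            )
        )
    for i in range(5):
        pos = 3_000 + i * 5_000
        loci.append(
            PlantedLocus(
                locus_id=f"noise_{i + 1:02d}",
                interval=GenomicInterval("chrT1", pos, pos + 300, "+"),
                biotype_class="noise",
                depth=4,  # below the default number-reads filter
                expected_verdict="rejected",
            )
        )
    return generate(loci, seed)


def repetitive_family_scenario(seed: int = 0, copies: int = 3, depth: int = 30) -> SyntheticDataset:
    """A multi-copy RNA family: every read aligns once per copy, so all
    copies share all reads and must form a clique in the cluster graph."""
    locus = PlantedLocus(
        locus_id="family_trna",
        interval=GenomicInterval("chrT1", 2_000, 2_075, "+"),
        biotype_class="trna_like",
        copies=copies,
        depth=depth,
    )
    return generate([locus], seed)


def two_stack_reads() -> List[AlignedRead]:
    """Boundary-optimizer fixture: a dense 22-nt stack (50 reads), a dense
    100-nt stack (30 reads), and 5 low-weight reads spanning the gap, all
    chained into one cluster."""
    reads: List[AlignedRead] = []
    for i in range(50):
        reads.append(
            AlignedRead(
                read_id=f"stackA_r{i:03d}",
                interval=GenomicInterval("chrT1", 1_000, 1_022, "+"),
                cigar="22M",
                hit_count=1,
                multiplicity="unique",
            )
        )
    for i in range(30):
        reads.append(
            AlignedRead(
                read_id=f"stackB_r{i:03d}",
                interval=GenomicInterval("chrT1", 1_100, 1_200, "+"),
                cigar="100M",
                hit_count=1,
                multiplicity="unique",
            )
        )
    for i in range(5):
        reads.append(
            AlignedRead(
                read_id=f"bridge_r{i:03d}",
                interval=GenomicInterval("chrT1", 1_010, 1_110, "+"),
                cigar="100M",
                hit_count=1,
                multiplicity="unique",
            )
        )
    return reads


# ---------------------------------------------------------------------------
# truth-table evaluation


@dataclass
class EvalResult:
    tp: int
    fn: int
    fp: int
    detail: Dict[str, str] = field(default_factory=dict)

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def f1(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / denom if denom else 0.0


def evaluate(
    truth: Sequence[PlantedLocus],
    results: Sequence[ClassifiedCluster],
    count_threshold: int = 5,
) -> EvalResult:
    """Score pipeline results against the planted truth.

    A planted small-RNA locus with simulated depth > ``count_threshold``
    is a true positive when some group with a non-rejected cluster
    contains a cluster overlapping any of the locus's copies, and a false
    negative otherwise. A non-rejected cluster whose group-deduplicated
    count exceeds the threshold but overlaps no planted small-RNA locus
    is a false positive.
    """
    positives = [
        t
        for t in truth
        if t.biotype_class in LENGTH_CLASSES and t.depth > count_threshold
    ]
    groups: Dict[str, List[ClassifiedCluster]] = {}
    for item in results:
        groups.setdefault(item.group_id, []).append(item)
    live_groups = {
        gid: items
        for gid, items in groups.items()
        if any(i.verdict != "rejected" for i in items)
    }

    def group_overlaps(items: List[ClassifiedCluster], locus: PlantedLocus) -> bool:
        return any(
            item.cluster.interval.overlaps(copy_iv)
            for item in items
            for copy_iv in locus.copy_intervals()
        )

    detail: Dict[str, str] = {}
    tp = fn = 0
    for locus in positives:
        if any(group_overlaps(items, locus) for items in live_groups.values()):
            tp += 1
            detail[locus.locus_id] = "TP"
        else:
            fn += 1
            detail[locus.locus_id] = "FN"

    fp = 0
    for item in results:
        if item.verdict == "rejected":
            continue
        if item.expression.group_deduplicated_count <= count_threshold:
            continue
        over_truth = any(
            item.cluster.interval.overlaps(copy_iv)
            for locus in positives
            for copy_iv in locus.copy_intervals()
        )
        if not over_truth:
            fp += 1
            detail[item.cluster.cluster_id] = "FP"
    return EvalResult(tp=tp, fn=fn, fp=fp, detail=detail)
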