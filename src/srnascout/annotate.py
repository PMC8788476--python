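"""GTF annotation loading, interval indexing, and Jaccard-scored overlap.

Annotation comes in as GTF (1-based inclusive; converted to 0-based
half-open on load) and is bucketed into four categories by biotype:
``small_rna``, ``protein_coding``, ``pseudogene``, ``lncrna``. Small-RNA
features are held as single transcript-level intervals (the provided
small-RNA sets are unspliced); protein-coding features are held at exon
granularity so the "overlaps a protein-coding exon" test sees introns as
clean.

Overlap between a cluster and a feature is scored with the Jaccard index
on base-pair lengths: |intersection| / |union|.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import gffutils
from intervaltree import IntervalTree

from srnascout.alignments import GenomicInterval
from srnascout.clustering import ReadCluster

logger = logging.getLogger(__name__)

#: Biotype -> category mapping. Biotypes are matched case-insensitively;
#: anything containing "pseudogene" maps to pseudogene, recognised coding
#: and long-noncoding biotypes to their categories, and everything else to
#: small_rna (the small-RNA annotation sets use many biotype spellings).
LNCRNA_BIOTYPES = {
    "lncrna", "lincrna", "antisense", "sense_intronic", "sense_overlapping",
    "processed_transcript", "3prime_overlapping_ncrna",
}
CODING_BIOTYPES = {"protein_coding", "mrna"}


def biotype_category(biotype: str) -> str:
    b = biotype.strip().lower()
    if "pseudogene" in b:
        return "pseudogene"
    if b in CODING_BIOTYPES:
        return "protein_coding"
    if b in LNCRNA_BIOTYPES:
        return "lncrna"
    return "small_rna"


@dataclass(frozen=True)
class AnnotationFeature:
    feature_id: str
    name: str
    biotype: str
    category: str
    interval: GenomicInterval
    is_exon: bool = False


@dataclass(frozen=True)
class AnnotationHit:
    """A feature overlapping a cluster, with its Jaccard score (> 0)."""

    feature: AnnotationFeature
    jaccard: float


class AnnotationIndex:
    """Per-chromosome interval trees over annotation features."""

    def __init__(self, features: Iterable[AnnotationFeature] = ()) -> None:
        self.features: List[AnnotationFeature] = []
        self._trees: Dict[str, IntervalTree] = {}
        for f in features:
            self.add(f)

    def add(self, feature: AnnotationFeature) -> None:
        self.features.append(feature)
        tree = self._trees.setdefault(feature.interval.chrom, IntervalTree())
        tree.addi(feature.interval.start, feature.interval.end, feature)

    def extend(self, features: Iterable[AnnotationFeature]) -> None:
        for f in features:
            self.add(f)

    def query(self, interval: GenomicInterval) -> List[AnnotationFeature]:
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(interval.start, interval.end)]

    def __len__(self) -> int:
        return len(self.features)


_BIOTYPE_KEYS = (
    "transcript_biotype",
    "gene_biotype",
    "biotype",
    "transcript_type",
    "gene_type",
    "type",
)
_NAME_KEYS = ("transcript_name", "gene_name", "Name", "name")


def _attr(record, keys) -> Optional[str]:
    for key in keys:
        values = record.attributes.get(key)
        if values:
            return values[0]
    return None


def load_annotation(
    path: str, index: Optional[AnnotationIndex] = None
) -> AnnotationIndex:
    """Load a GTF into an interval-queryable feature index.

    Records must carry a ``transcript_id`` attribute (records without one
    are skipped with a warning). Features of one transcript are merged to
    a single span, except protein-coding transcripts with exon records,
    which contribute one feature per exon. Pass an existing ``index`` to
    merge several GTFs (e.g. a small-RNA set plus a host-gene set).
    """
    try:
        db = gffutils.create_db(
            path,
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # noqa: BLE001 - surface as parse error
        raise ValueError(f"failed to parse GTF {path}: {exc}") from exc

    groups: Dict[str, List] = {}
    n_skipped = 0
    for rec in db.all_features():
        tid = _attr(rec, ("transcript_id",))
        if tid is None:
            n_skipped += 1
            continue
        groups.setdefault(tid, []).append(rec)
    if n_skipped:
        logger.warning("%d GTF records without transcript_id skipped", n_skipped)

    if index is None:
        index = AnnotationIndex()
    for tid, records in groups.items():
        first = records[0]
        biotype = _attr(first, _BIOTYPE_KEYS) or first.source or "unknown"
        category = biotype_category(biotype)
        name = _attr(first, _NAME_KEYS) or tid
        strand = first.strand if first.strand in ("+", "-") else "."
        exons = [r for r in records if r.featuretype == "exon"]
        if category == "protein_coding" and exons:
            for i, exon in enumerate(exons, start=1):
                index.add(
                    AnnotationFeature(
                        feature_id=tid,
                        name=f"{name}_exon{i}",
                        biotype=biotype,
                        category=category,
                        interval=GenomicInterval(
                            exon.seqid, exon.start - 1, exon.end, strand
                        ),
                        is_exon=True,
                    )
                )
        else:
            start = min(r.start for r in records) - 1
            end = max(r.end for r in records)
            index.add(
                AnnotationFeature(
                    feature_id=tid,
                    name=name,
                    biotype=biotype,
                    category=category,
                    interval=GenomicInterval(first.seqid, start, end, strand),
                )
            )
    return index


def jaccard_score(a: GenomicInterval, b: GenomicInterval) -> float:
    """Base-pair intersection over union; 0 for different chromosomes."""
    inter = a.intersection_length(b)
    if inter == 0:
        return 0.0
    union = a.length + b.length - inter
    return inter / union


def _strand_compatible(cluster_iv: GenomicInterval, feature: AnnotationFeature) -> bool:
    # same-strand required for small-RNA hits when both strands are known;
    # unstranded features (or clusters) match either strand
    if feature.category != "small_rna":
        return True
    if cluster_iv.strand not in ("+", "-") or feature.interval.strand not in ("+", "-"):
        return True
    return cluster_iv.strand == feature.interval.strand


def annotate_cluster(
    cluster: ReadCluster, annotation: AnnotationIndex
) -> List[AnnotationHit]:
    """All features overlapping a cluster, best Jaccard first.

    Ties prefer small-RNA features, then longer features, then the
    lexicographically smallest feature id.
    """
    hits = []
    for feature in annotation.query(cluster.interval):
        if not _strand_compatible(cluster.interval, feature):
            continue
        score = jaccard_score(cluster.interval, feature.interval)
        if score > 0:
            hits.append(AnnotationHit(feature=feature, jaccard=score))
    hits.sort(
        key=lambda h: (
            -h.jaccard,
            0 if h.feature.category == "small_rna" else 1,
            -h.feature.interval.length,
            h.feature.feature_id,
        )
    )
    return hits


def has_coding_exon_overlap(
    cluster: ReadCluster, annotation: AnnotationIndex
) -> bool:
    """True iff the cluster overlaps any protein-coding exon feature."""
    return any(
        f.category == "protein_coding"
        for f in annotation.query(cluster.interval)
    )
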