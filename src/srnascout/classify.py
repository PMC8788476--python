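"""Decision-tree classification of cluster-graph nodes and Jaccard
refinement into the four final verdicts.

Every graph component is traversed. Single-node components bypass the
tree and are reported directly. In a multi-node component the largest
node is accepted outright (annotated when it overlaps small-RNA
annotation, else unannotated when deep enough); each smaller node then
runs the gauntlet:

1. fewer than ``number_reads`` alignments        -> low quality,
2. > ``ov_with_largest`` of its alignments shared
   with the largest node                          -> low quality,
3. unique-read fraction > ``percent_uniq``        -> accept,
4. < 50% of alignments shared with other nodes    -> accept,
5. more than ``unique_reads`` unique alignments   -> accept,
6. otherwise                                      -> low quality.

Accepted nodes become provisionally annotated (>= 1 small-RNA hit) or
unannotated. Refinement then applies the Jaccard cutoff
(``jaccard_index``), the 17-200 nt length window, and the
protein-coding-exon veto, yielding annotated / close_proximity /
unannotated / rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from srnascout.annotate import (
    AnnotationHit,
    AnnotationIndex,
    annotate_cluster,
    has_coding_exon_overlap,
)
from srnascout.clustering import ReadCluster
from srnascout.network import ClusterGraph


@dataclass(frozen=True)
class ClassifierParams:
    """Decision-tree and refinement thresholds (CLI flag names noted).

    number_reads    : minimum alignments per cluster (number-reads, 5)
    ov_with_largest : max fraction shared with the largest node
                      (ov-with-largest, 0.75)
    percent_uniq    : unique-read fraction for acceptance (percent-uniq, 0.5)
    unique_reads    : minimum unique-read count fallback (unique-reads, 2)
    jaccard_index   : annotation acceptance score (jaccard-index, 0.3)
    min_len/max_len : admissible cluster length range, 17-200 nt
    """

    number_reads: int = 5
    ov_with_largest: float = 0.75
    percent_uniq: float = 0.5
    unique_reads: int = 2
    jaccard_index: float = 0.3
    min_len: int = 17
    max_len: int = 200

    def __post_init__(self) -> None:
        for name in ("ov_with_largest", "percent_uniq", "jaccard_index"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if not (0 < self.min_len < self.max_len):
            raise ValueError("require 0 < min_len < max_len")


@dataclass(frozen=True)
class Expression:
    n_total: int
    n_unique: int
    n_shared: int
    group_deduplicated_count: int


@dataclass
class ClassifiedCluster:
    cluster: ReadCluster
    verdict: str  # annotated | close_proximity | unannotated | rejected
    reject_reason: Optional[str]
    best_hit: Optional[AnnotationHit]
    candidate_hits: List[AnnotationHit]
    group_id: str
    expression: Expression


@dataclass(frozen=True)
class Provisional:
    label: str  # annotated | unannotated | low_quality
    reason: Optional[str] = None  # reject reason when low_quality


def _largest_node(nodes: Sequence[ReadCluster]) -> ReadCluster:
    """Greatest n_total; ties by n_unique, then leftmost coordinate."""
    return max(
        nodes,
        key=lambda c: (c.n_total, c.n_unique, -c.interval.start, c.cluster_id),
    )


def _shared_fraction_with(node: ReadCluster, other_ids: Set[str]) -> float:
    shared = sum(1 for r in node.members if r.read_id in other_ids)
    return shared / node.n_total


def classify_component(
    nodes: Sequence[ReadCluster],
    has_hits: Dict[str, bool],
    params: Optional[ClassifierParams] = None,
) -> Dict[str, Provisional]:
    """Provisional class per node of one graph component.

    ``has_hits[cluster_id]`` states whether the node overlaps at least one
    small-RNA annotation feature.
    """
    if params is None:
        params = ClassifierParams()

    def by_hits(node: ReadCluster) -> Provisional:
        return Provisional("annotated" if has_hits[node.cluster_id] else "unannotated")

    result: Dict[str, Provisional] = {}
    if len(nodes) == 1:
        node = nodes[0]
        if has_hits[node.cluster_id]:
            result[node.cluster_id] = Provisional("annotated")
        elif node.n_total >= params.number_reads:
            result[node.cluster_id] = Provisional("unannotated")
        else:
            result[node.cluster_id] = Provisional("low_quality", "low_reads")
        return result

    largest = _largest_node(nodes)
    if has_hits[largest.cluster_id]:
        result[largest.cluster_id] = Provisional("annotated")
    elif largest.n_total >= params.number_reads:
        result[largest.cluster_id] = Provisional("unannotated")
    else:
        result[largest.cluster_id] = Provisional("low_quality", "low_reads")

    largest_ids = largest.read_ids
    for node in nodes:
        if node.cluster_id == largest.cluster_id:
            continue
        if node.n_total < params.number_reads:
            result[node.cluster_id] = Provisional("low_quality", "low_reads")
            continue
        if _shared_fraction_with(node, largest_ids) > params.ov_with_largest:
            result[node.cluster_id] = Provisional(
                "low_quality", "shared_with_largest"
            )
            continue
        if node.n_unique / node.n_total > params.percent_uniq:
            result[node.cluster_id] = by_hits(node)
            continue
        other_ids: Set[str] = set()
        for other in nodes:
            if other.cluster_id != node.cluster_id:
                other_ids |= other.read_ids
        if _shared_fraction_with(node, other_ids) < 0.5:
            result[node.cluster_id] = by_hits(node)
            continue
        if node.n_unique > params.unique_reads:
            result[node.cluster_id] = by_hits(node)
            continue
        result[node.cluster_id] = Provisional("low_quality", "repeat_only")
    return result


def count_expression(nodes: Sequence[ReadCluster]) -> int:
    """Group-level expression: each distinct read id counted once across
    the component, so a multi-copy family is not multiply counted."""
    ids: Set[str] = set()
    for node in nodes:
        ids |= node.read_ids
    return len(ids)


def refine(
    cluster: ReadCluster,
    provisional: Provisional,
    hits: Sequence[AnnotationHit],
    coding_overlap: bool,
    params: Optional[ClassifierParams] = None,
) -> Tuple[str, Optional[str], Optional[AnnotationHit]]:
    """Final verdict for one provisionally classified cluster.

    Returns (verdict, reject_reason, best_hit). The best hit is the
    top-scoring small-RNA hit (hits are pre-sorted by annotate_cluster).
    """
    if params is None:
        params = ClassifierParams()
    length = cluster.interval.length
    length_ok = params.min_len <= length <= params.max_len
    small_hits = [h for h in hits if h.feature.category == "small_rna"]
    best = small_hits[0] if small_hits else None

    if provisional.label == "low_quality":
        return "rejected", provisional.reason or "low_reads", best

    if provisional.label == "annotated":
        if best is not None and best.jaccard > params.jaccard_index:
            return "annotated", None, best
        if length_ok and not coding_overlap:
            return "close_proximity", None, best
        if coding_overlap:
            return "rejected", "coding_overlap", best
        return "rejected", "jaccard_and_length_fail", best

    # provisional unannotated: coding-exon transcription is vetoed, then
    # the length window applies
    if coding_overlap:
        return "rejected", "coding_overlap", None
    if not length_ok:
        return "rejected", "length_fail", None
    return "unannotated", None, None


def classify_graph(
    graph: ClusterGraph,
    annotation: AnnotationIndex,
    params: Optional[ClassifierParams] = None,
) -> List[ClassifiedCluster]:
    """Classify every node of a cluster graph: decision tree per
    component, then Jaccard/length/coding refinement per node."""
    if params is None:
        params = ClassifierParams()

    # global shared-read bookkeeping for the n_shared output column
    owners: Dict[str, int] = {}
    for cluster in graph.clusters.values():
        for rid in cluster.read_ids:
            owners[rid] = owners.get(rid, 0) + 1

    results: List[ClassifiedCluster] = []
    for comp_idx, comp_ids in enumerate(graph.components):
        nodes = [graph.clusters[cid] for cid in comp_ids]
        group_id = f"group_{comp_idx + 1:05d}"
        hits_by_node = {cid: annotate_cluster(graph.clusters[cid], annotation) for cid in comp_ids}
        has_hits = {
            cid: any(h.feature.category == "small_rna" for h in hits_by_node[cid])
            for cid in comp_ids
        }
        provisional = classify_component(nodes, has_hits, params)
        group_count = count_expression(nodes)
        for cid in comp_ids:
            cluster = graph.clusters[cid]
            hits = hits_by_node[cid]
            coding = has_coding_exon_overlap(cluster, annotation)
            verdict, reason, best = refine(
                cluster, provisional[cid], hits, coding, params
            )
            n_shared = sum(
                1 for r in cluster.members if owners.get(r.read_id, 0) > 1
            )
            results.append(
                ClassifiedCluster(
                    cluster=cluster,
                    verdict=verdict,
                    reject_reason=reason,
                    best_hit=best,
                    candidate_hits=hits,
                    group_id=group_id,
                    expression=Expression(
                        n_total=cluster.n_total,
                        n_unique=cluster.n_unique,
                        n_shared=n_shared,
                        group_deduplicated_count=group_count,
                    ),
                )
            )
    return results
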