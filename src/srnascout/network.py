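"""Cluster graph built from shared multi-mapped reads.

Nodes are read clusters; two nodes are linked when more than half of the
alignments of at least one node belong to reads that also align in the
other node. Connected components are labelled by shape:

* ``single`` - an isolated cluster (no qualifying shared reads),
* ``clique`` - every pair linked; the signature of a multi-copy RNA
  family, whose expression must be counted once,
* ``star``   - one hub linked to every leaf with no leaf-leaf links; the
  signature of satellite false-positive clusters around one true locus,
* ``other``  - any remaining topology.

Each component carries a group id and a representative node (most unique
reads, ties by total reads then leftmost coordinate) used for
group-level, read-id-deduplicated expression counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, FrozenSet, List, Set, Tuple

import networkx as nx

from srnascout.clustering import ReadCluster


def shared_reads(a: ReadCluster, b: ReadCluster) -> Set[str]:
    """Read ids with at least one alignment among each cluster's members."""
    return a.read_ids & b.read_ids


def share_fraction(a: ReadCluster, b: ReadCluster, count_read_ids: bool = False) -> float:
    """Fraction of a's alignments (or distinct read ids) shared with b."""
    common = shared_reads(a, b)
    if count_read_ids:
        return len(common) / len(a.read_ids)
    n_shared = sum(1 for r in a.members if r.read_id in common)
    return n_shared / a.n_total


@dataclass
class ClusterGraph:
    clusters: Dict[str, ReadCluster]
    graph: nx.Graph
    components: List[List[str]]
    component_shape: List[str]
    node_component: Dict[str, int]

    def component_of(self, cluster_id: str) -> List[str]:
        return self.components[self.node_component[cluster_id]]

    def shape_of(self, cluster_id: str) -> str:
        return self.component_shape[self.node_component[cluster_id]]

    def representative(self, comp_index: int) -> str:
        """Representative node of a component: most unique reads, ties by
        n_total, then leftmost coordinate."""
        ids = self.components[comp_index]
        return max(
            ids,
            key=lambda cid: (
                self.clusters[cid].n_unique,
                self.clusters[cid].n_total,
                -self.clusters[cid].interval.start,
                cid,
            ),
        )

    def edge_list(self) -> str:
        """TSV edge dump (cluster_a, cluster_b, shared_read_count)."""
        lines = []
        for a, b, data in sorted(self.graph.edges(data=True)):
            lines.append(f"{a}\t{b}\t{data['shared_read_count']}")
        return "\n".join(lines) + ("\n" if lines else "")


def _component_shape(g: nx.Graph, nodes: List[str]) -> str:
    n = len(nodes)
    if n == 1:
        return "single"
    sub = g.subgraph(nodes)
    m = sub.number_of_edges()
    if m == n * (n - 1) // 2:
        return "clique"
    degrees = dict(sub.degree())
    hubs = [v for v, d in degrees.items() if d == n - 1]
    if n >= 3 and m == n - 1 and len(hubs) == 1:
        return "star"
    return "other"


def build_graph(
    clusters: List[ReadCluster], count_read_ids: bool = False
) -> ClusterGraph:
    """Link clusters sharing >50% of alignments in at least one direction.

    Candidate pairs are found through an inverted read-id index, so only
    clusters that actually share a read are compared.
    """
    by_id = {c.cluster_id: c for c in clusters}
    if len(by_id) != len(clusters):
        raise ValueError("duplicate cluster ids")

    g = nx.Graph()
    g.add_nodes_from(by_id)

    read_index: Dict[str, Set[str]] = {}
    for c in clusters:
        for rid in c.read_ids:
            read_index.setdefault(rid, set()).add(c.cluster_id)

    candidate_pairs: Set[Tuple[str, str]] = set()
    for owners in read_index.values():
        if len(owners) > 1:
            for pair in combinations(sorted(owners), 2):
                candidate_pairs.add(pair)

    for a_id, b_id in candidate_pairs:
        a, b = by_id[a_id], by_id[b_id]
        if (
            share_fraction(a, b, count_read_ids) > 0.5
            or share_fraction(b, a, count_read_ids) > 0.5
        ):
            g.add_edge(a_id, b_id, shared_read_count=len(shared_reads(a, b)))

    components = [sorted(comp) for comp in nx.connected_components(g)]
    components.sort(key=lambda ids: ids[0])
    shapes = [_component_shape(g, ids) for ids in components]
    node_component = {
        cid: idx for idx, ids in enumerate(components) for cid in ids
    }
    return ClusterGraph(
        clusters=by_id,
        graph=g,
        components=components,
        component_shape=shapes,
        node_component=node_component,
    )


def filter_shared_reads_naive(
    clusters: List[ReadCluster],
    number_reads: int = 5,
    count_read_ids: bool = False,
) -> List[ReadCluster]:
    """Baseline multi-mapped handling: discard every read shared between
    graph nodes, then re-apply the minimum-read filter.

    Used only for comparison against the network + decision-tree route;
    on repetitive families it wipes out all copies.
    """
    graph = build_graph(clusters, count_read_ids)
    shared: Set[str] = set()
    for a_id, b_id in graph.graph.edges():
        shared |= shared_reads(graph.clusters[a_id], graph.clusters[b_id])
    # a read present in >= 2 nodes is removed from all of them, even nodes
    # not linked by an edge
    owners_count: Dict[str, int] = {}
    for c in clusters:
        for rid in c.read_ids:
            owners_count[rid] = owners_count.get(rid, 0) + 1
    shared |= {rid for rid, n in owners_count.items() if n > 1}

    result = []
    for c in clusters:
        members = [r for r in c.members if r.read_id not in shared]
        if len(members) >= number_reads:
            result.append(
                ReadCluster(cluster_id=c.cluster_id, members=members)
            )
    return result
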