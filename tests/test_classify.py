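"""Decision-tree classification and Jaccard refinement."""

import pytest

from srnascout.alignments import GenomicInterval
from srnascout.annotate import AnnotationFeature, AnnotationHit
from srnascout.classify import (
    ClassifierParams,
    Provisional,
    classify_component,
    count_expression,
    refine,
)
from srnascout.clustering import ReadCluster

PARAMS = ClassifierParams()


def _component(make_read, t, u, s_largest, s_other, with_third=True):
    """A component with a dominant node L, a node under test X with ``t``
    alignments (``u`` unique, ``s_largest`` shared with L, ``s_other``
    shared with a third node), and optionally that third node."""
    largest = [make_read(0, 50, f"L{i}") for i in range(16)]
    third = [make_read(40_000, 40_050, f"T{i}") for i in range(3)]
    test = [make_read(1000, 1040, f"u{i}") for i in range(u)]
    for i in range(s_largest):
        rid = f"sl{i}"
        largest.append(make_read(10 + i, 40 + i, rid, multiplicity="multi"))
        test.append(make_read(1000 + i, 1030 + i, rid, multiplicity="multi"))
    for i in range(s_other):
        rid = f"so{i}"
        third.append(make_read(40_010 + i, 40_040 + i, rid, multiplicity="multi"))
        test.append(make_read(1000 + i, 1030 + i, rid, multiplicity="multi"))
    for i in range(t - u - s_largest - s_other):
        test.append(make_read(1000 + i, 1030 + i, f"m{i}", multiplicity="multi"))
    nodes = [
        ReadCluster("L", largest),
        ReadCluster("X", test),
    ]
    if with_third:
        nodes.append(ReadCluster("T", third))
    return nodes


def _oracle(t, u, s_largest, s_other, hits, params=PARAMS):
    """Independently coded truth table for a smaller node."""
    accept = "annotated" if hits else "unannotated"
    if t < params.number_reads:
        return "low_quality"
    if s_largest / t > params.ov_with_largest:
        return "low_quality"
    if u / t > params.percent_uniq:
        return accept
    if (s_largest + s_other) / t < 0.5:
        return accept
    if u > params.unique_reads:
        return accept
    return "low_quality"


def test_decision_tree_matches_truth_table_oracle(make_read):
    """Exhaustive grid over node states: total reads 1-12, every split of
    unique / shared-with-largest / shared-with-other reads, with and
    without annotation hits."""
    n_states = 0
    for t in range(1, 13):
        for u in range(0, t + 1):
            for s_l in range(0, t - u + 1):
                for s_o in range(0, t - u - s_l + 1):
                    nodes = _component(make_read, t, u, s_l, s_o)
                    for hits in (True, False):
                        has_hits = {"L": True, "X": hits, "T": False}
                        got = classify_component(nodes, has_hits, PARAMS)
                        assert got["X"].label == _oracle(t, u, s_l, s_o, hits), (
                            t, u, s_l, s_o, hits,
                        )
                        n_states += 1
    assert n_states == 2 * sum(1 for t in range(1, 13) for u in range(t + 1)
                               for a in range(t - u + 1) for b in range(t - u - a + 1))


@pytest.mark.parametrize(
    "t,u,s_l,s_o,hits,expected",
    [
        (4, 4, 0, 0, True, "low_quality"),    # below number-reads
        (10, 0, 8, 0, True, "low_quality"),   # 80% shared with largest
        (10, 6, 0, 0, False, "unannotated"),  # unique fraction 0.6, no hits
        (10, 3, 4, 2, True, "annotated"),     # falls through to unique-reads rule
        (10, 2, 4, 2, False, "low_quality"),  # n_unique == unique_reads: not >
    ],
)
def test_decision_tree_documented_branches(make_read, t, u, s_l, s_o, hits, expected):
    nodes = _component(make_read, t, u, s_l, s_o)
    got = classify_component(nodes, {"L": True, "X": hits, "T": False}, PARAMS)
    assert got["X"].label == expected


def test_largest_node_accepted_outright(make_read):
    nodes = _component(make_read, 10, 0, 8, 0)
    got = classify_component(nodes, {"L": True, "X": False, "T": False}, PARAMS)
    assert got["L"].label == "annotated"
    got = classify_component(nodes, {"L": False, "X": False, "T": False}, PARAMS)
    assert got["L"].label == "unannotated"


def test_single_node_bypasses_tree(make_read):
    node = ReadCluster("S", [make_read(0, 30, f"r{i}") for i in range(5)])
    assert classify_component([node], {"S": True}, PARAMS)["S"].label == "annotated"
    assert classify_component([node], {"S": False}, PARAMS)["S"].label == "unannotated"
    shallow = ReadCluster("S", [make_read(0, 30, f"r{i}") for i in range(4)])
    got = classify_component([shallow], {"S": False}, PARAMS)["S"]
    assert (got.label, got.reason) == ("low_quality", "low_reads")


def test_raising_number_reads_is_monotone(make_read):
    """A stricter read filter never yields more accepted nodes."""
    nodes = _component(make_read, 7, 4, 2, 1)
    prev_accepted = None
    for nr in range(1, 10):
        params = ClassifierParams(number_reads=nr)
        got = classify_component(nodes, {"L": True, "X": True, "T": True}, params)
        accepted = sum(1 for p in got.values() if p.label != "low_quality")
        if prev_accepted is not None:
            assert accepted <= prev_accepted
        prev_accepted = accepted


# --- refinement ------------------------------------------------------------


def _hit(jaccard, category="small_rna", fid="feat1", biotype="miRNA"):
    return AnnotationHit(
        feature=AnnotationFeature(
            feature_id=fid,
            name=fid,
            biotype=biotype,
            category=category,
            interval=GenomicInterval("chrT1", 0, 100, "+"),
        ),
        jaccard=jaccard,
    )


def _cluster_of_length(make_read, length, n=6):
    return ReadCluster(
        "c1", [make_read(1000, 1000 + length, f"r{i}") for i in range(n)]
    )


def test_refine_annotated_above_jaccard_cutoff(make_read):
    cluster = _cluster_of_length(make_read, 80)
    verdict, reason, best = refine(
        cluster, Provisional("annotated"), [_hit(0.5)], False, PARAMS
    )
    assert verdict == "annotated" and reason is None and best.jaccard == 0.5


def test_refine_low_jaccard_goes_close_proximity(make_read):
    cluster = _cluster_of_length(make_read, 80)
    verdict, _, _ = refine(
        cluster, Provisional("annotated"), [_hit(0.2)], False, PARAMS
    )
    assert verdict == "close_proximity"


def test_refine_low_jaccard_with_coding_overlap_rejected(make_read):
    cluster = _cluster_of_length(make_read, 80)
    verdict, reason, _ = refine(
        cluster, Provisional("annotated"), [_hit(0.2)], True, PARAMS
    )
    assert (verdict, reason) == ("rejected", "coding_overlap")


def test_refine_length_filters(make_read):
    long_cluster = _cluster_of_length(make_read, 250)
    verdict, reason, _ = refine(
        long_cluster, Provisional("unannotated"), [], False, PARAMS
    )
    assert (verdict, reason) == ("rejected", "length_fail")
    ok_cluster = _cluster_of_length(make_read, 120)
    verdict, _, _ = refine(
        ok_cluster, Provisional("unannotated"), [], False, PARAMS
    )
    assert verdict == "unannotated"


def test_refine_jaccard_boundary_not_strict_greater(make_read):
    # a best score exactly at the cutoff does not annotate
    cluster = _cluster_of_length(make_read, 80)
    verdict, _, _ = refine(
        cluster, Provisional("annotated"), [_hit(PARAMS.jaccard_index)], False, PARAMS
    )
    assert verdict == "close_proximity"


# --- expression ------------------------------------------------------------


def test_group_deduplicated_count(make_read):
    clique = []
    for copy in range(3):
        base = copy * 10_000
        clique.append(
            ReadCluster(
                f"copy{copy}",
                [
                    make_read(base, base + 70, f"fam{i}", multiplicity="multi")
                    for i in range(30)
                ],
            )
        )
    assert count_expression(clique) == 30  # not 90

    single = ReadCluster("s", [make_read(0, 30, f"u{i}") for i in range(10)])
    assert count_expression([single]) == 10

    two = [
        ReadCluster(
            "a",
            [make_read(0, 30, f"sh{i}", multiplicity="multi") for i in range(5)]
            + [make_read(0, 30, f"own{i}") for i in range(2)],
        ),
        ReadCluster(
            "b",
            [make_read(900, 930, f"sh{i}", multiplicity="multi") for i in range(5)],
        ),
    ]
    assert count_expression(two) == 7


def test_group_count_bounded_by_total(make_read):
    clusters = [
        ReadCluster("a", [make_read(0, 30, f"r{i}") for i in range(4)]),
        ReadCluster("b", [make_read(100, 130, f"r{i}", multiplicity="multi") for i in range(2, 6)]),
    ]
    total = sum(c.n_total for c in clusters)
    assert count_expression(clusters) <= total
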