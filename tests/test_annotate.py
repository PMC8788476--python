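"""GTF loading, Jaccard scoring, and cluster annotation."""

import numpy as np
import pytest

from srnascout.alignments import GenomicInterval
from srnascout.annotate import (
    AnnotationFeature,
    AnnotationIndex,
    annotate_cluster,
    biotype_category,
    has_coding_exon_overlap,
    jaccard_score,
    load_annotation,
)
from srnascout.clustering import ReadCluster


GTF = """\
chrT1\ttest\ttranscript\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "mir1"; gene_biotype "miRNA";
chrT1\ttest\ttranscript\t501\t580\t.\t+\t.\tgene_id "g2"; transcript_id "trna1"; gene_biotype "tRNA";
chrT1\ttest\ttranscript\t1001\t2000\t.\t+\t.\tgene_id "g3"; transcript_id "pc1"; gene_biotype "protein_coding";
chrT1\ttest\texon\t1001\t1100\t.\t+\t.\tgene_id "g3"; transcript_id "pc1"; gene_biotype "protein_coding";
chrT1\ttest\texon\t1901\t2000\t.\t+\t.\tgene_id "g3"; transcript_id "pc1"; gene_biotype "protein_coding";
chrT1\ttest\ttranscript\t3001\t3100\t.\t-\t.\tgene_id "g4"; transcript_id "mir2"; gene_biotype "miRNA";
"""


@pytest.fixture
def annotation(tmp_path):
    path = tmp_path / "anno.gtf"
    path.write_text(GTF)
    return load_annotation(str(path))


def make_cluster(make_read, start, end, strand="+", n=6):
    reads = [
        make_read(start, end, f"c{start}_{i}", strand=strand) for i in range(n)
    ]
    return ReadCluster(cluster_id=f"c{start}", members=reads)


def test_gtf_coordinates_converted_to_half_open(annotation):
    mir1 = next(f for f in annotation.features if f.feature_id == "mir1")
    assert (mir1.interval.start, mir1.interval.end) == (100, 200)


def test_biotype_category_mapping(annotation):
    by_id = {f.feature_id: f for f in annotation.features}
    assert by_id["mir1"].category == "small_rna"
    assert by_id["trna1"].category == "small_rna"
    assert by_id["pc1"].category == "protein_coding"
    assert biotype_category("transcribed_unprocessed_pseudogene") == "pseudogene"
    assert biotype_category("lincRNA") == "lncrna"


def test_protein_coding_held_at_exon_granularity(annotation):
    exons = [f for f in annotation.features if f.feature_id == "pc1"]
    assert len(exons) == 2 and all(f.is_exon for f in exons)
    assert {(f.interval.start, f.interval.end) for f in exons} == {
        (1000, 1100),
        (1900, 2000),
    }


def test_records_without_transcript_id_skipped(tmp_path):
    gtf = tmp_path / "partial.gtf"
    gtf.write_text(
        'chrT1\tt\ttranscript\t1\t50\t.\t+\t.\tgene_id "g";\n'
        'chrT1\tt\ttranscript\t101\t150\t.\t+\t.\tgene_id "g2"; transcript_id "ok1"; gene_biotype "miRNA";\n'
    )
    index = load_annotation(str(gtf))
    assert [f.feature_id for f in index.features] == ["ok1"]


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ((0, 100), (0, 100), 1.0),
        ((0, 100), (200, 300), 0.0),
        ((0, 100), (50, 150), 50 / 150),
    ],
)
def test_jaccard_examples(a, b, expected):
    iva = GenomicInterval("chrT1", a[0] + 1000, a[1] + 1000)
    ivb = GenomicInterval("chrT1", b[0] + 1000, b[1] + 1000)
    assert jaccard_score(iva, ivb) == pytest.approx(expected)


def test_jaccard_matches_per_base_set_oracle():
    rng = np.random.default_rng(17)
    for _ in range(1000):
        s1, s2 = (int(x) for x in rng.integers(0, 300, size=2))
        l1, l2 = (int(x) for x in rng.integers(1, 200, size=2))
        a = GenomicInterval("chrT1", s1, s1 + l1)
        b = GenomicInterval("chrT1", s2, s2 + l2)
        set_a, set_b = set(range(s1, s1 + l1)), set(range(s2, s2 + l2))
        expected = len(set_a & set_b) / len(set_a | set_b)
        assert jaccard_score(a, b) == pytest.approx(expected)
        assert jaccard_score(b, a) == jaccard_score(a, b)  # symmetry


def test_annotate_cluster_best_hit_ordering(annotation, make_read):
    # cluster over mir1 exactly
    cluster = make_cluster(make_read, 100, 200)
    hits = annotate_cluster(cluster, annotation)
    assert hits[0].feature.feature_id == "mir1"
    assert hits[0].jaccard == pytest.approx(1.0)

    # no overlapping feature
    assert annotate_cluster(make_cluster(make_read, 10_000, 10_100), annotation) == []

    # jaccard descending across multiple hits
    wide = make_cluster(make_read, 480, 600)
    scores = [h.jaccard for h in annotate_cluster(wide, annotation)]
    assert scores == sorted(scores, reverse=True)


def test_small_rna_hits_require_matching_strand(annotation, make_read):
    plus = make_cluster(make_read, 3000, 3100, strand="+")
    minus = make_cluster(make_read, 3000, 3100, strand="-")
    assert annotate_cluster(plus, annotation) == []  # mir2 is minus-strand
    assert [h.feature.feature_id for h in annotate_cluster(minus, annotation)] == ["mir2"]


def test_coding_exon_overlap_flag(annotation, make_read):
    exonic = make_cluster(make_read, 1050, 1090)
    intronic = make_cluster(make_read, 1200, 1300)
    assert has_coding_exon_overlap(exonic, annotation)
    assert not has_coding_exon_overlap(intronic, annotation)


def test_annotate_matches_brute_force_scan(make_read):
    rng = np.random.default_rng(23)
    features = []
    for i in range(500):
        start = int(rng.integers(0, 20_000))
        length = int(rng.integers(20, 150))
        features.append(
            AnnotationFeature(
                feature_id=f"f{i}",
                name=f"f{i}",
                biotype="miRNA",
                category="small_rna",
                interval=GenomicInterval("chrT1", start, start + length, "+"),
            )
        )
    index = AnnotationIndex(features)
    for trial in range(50):
        start = int(rng.integers(0, 20_000))
        cluster = make_cluster(make_read, start, start + int(rng.integers(20, 200)))
        got = {h.feature.feature_id for h in annotate_cluster(cluster, index)}
        expected = {
            f.feature_id
            for f in features
            if f.interval.overlaps(cluster.interval)
        }
        assert got == expected
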