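"""BED-compliant TSV output tables and the run-level summary.

One row per classified cluster, routed to ``annotated.tsv``,
``close_proximity.tsv``, ``unannotated.tsv``, or ``rejected.tsv``. The
first six columns are valid BED6 (0-based half-open; the BED score is the
group-deduplicated read count capped at 1000). A ``summary.json`` with
per-verdict and per-biotype counts accompanies the tables.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional

from srnascout.classify import ClassifiedCluster

VERDICT_FILES = {
    "annotated": "annotated.tsv",
    "close_proximity": "close_proximity.tsv",
    "unannotated": "unannotated.tsv",
    "rejected": "rejected.tsv",
}

COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "n_total", "n_unique", "n_shared", "verdict", "group_id",
    "best_feature_id", "best_feature_biotype", "best_jaccard",
    "other_candidates", "reject_reason",
]


@dataclass(frozen=True)
class OutputRow:
    chrom: str
    start: int
    end: int
    name: str
    score: int
    strand: str
    n_total: int
    n_unique: int
    n_shared: int
    verdict: str
    group_id: str
    best_feature_id: str
    best_feature_biotype: str
    best_jaccard: str
    other_candidates: str
    reject_reason: str

    def to_line(self) -> str:
        return "\t".join(str(getattr(self, c)) for c in COLUMNS)

    @classmethod
    def from_line(cls, line: str) -> "OutputRow":
        parts = line.rstrip("\n").split("\t")
        if len(parts) != len(COLUMNS):
            raise ValueError(f"expected {len(COLUMNS)} columns, got {len(parts)}")
        kwargs = dict(zip(COLUMNS, parts))
        for key in ("start", "end", "score", "n_total", "n_unique", "n_shared"):
            kwargs[key] = int(kwargs[key])
        return cls(**kwargs)


def to_row(item: ClassifiedCluster) -> OutputRow:
    iv = item.cluster.interval
    best = item.best_hit
    # annotation columns are reported only when an annotation was accepted
    show_best = best is not None and item.verdict in ("annotated", "close_proximity")
    others = ""
    if show_best:
        others = ";".join(
            f"{h.feature.feature_id}:{h.jaccard:.4f}"
            for h in item.candidate_hits
            if h.feature is not best.feature
        )
    return OutputRow(
        chrom=iv.chrom,
        start=iv.start,
        end=iv.end,
        name=item.cluster.cluster_id,
        score=min(item.expression.group_deduplicated_count, 1000),
        strand=iv.strand,
        n_total=item.expression.n_total,
        n_unique=item.expression.n_unique,
        n_shared=item.expression.n_shared,
        verdict=item.verdict,
        group_id=item.group_id,
        best_feature_id=best.feature.feature_id if show_best else "",
        best_feature_biotype=best.feature.biotype if show_best else "",
        best_jaccard=f"{best.jaccard:.4f}" if show_best else "",
        other_candidates=others,
        reject_reason=item.reject_reason or "",
    )


def write_outputs(
    items: Iterable[ClassifiedCluster], outdir: str
) -> Dict[str, object]:
    """Write the four verdict tables plus summary.json; returns the
    summary dict."""
    os.makedirs(outdir, exist_ok=True)
    rows_by_verdict: Dict[str, List[OutputRow]] = {v: [] for v in VERDICT_FILES}
    biotype_counts: Dict[str, int] = {}
    for item in items:
        row = to_row(item)
        rows_by_verdict[row.verdict].append(row)
        if row.verdict == "annotated" and row.best_feature_biotype:
            biotype_counts[row.best_feature_biotype] = (
                biotype_counts.get(row.best_feature_biotype, 0) + 1
            )

    header = "#" + "\t".join(COLUMNS)
    for verdict, filename in VERDICT_FILES.items():
        rows = sorted(rows_by_verdict[verdict], key=lambda r: (r.chrom, r.start, r.end, r.name))
        with open(os.path.join(outdir, filename), "w") as fh:
            fh.write(header + "\n")
            for row in rows:
                fh.write(row.to_line() + "\n")

    summary = {
        "verdict_counts": {v: len(rows_by_verdict[v]) for v in VERDICT_FILES},
        "annotated_biotype_counts": dict(sorted(biotype_counts.items())),
        "n_clusters": sum(len(r) for r in rows_by_verdict.values()),
    }
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def read_rows(path: str) -> List[OutputRow]:
    """Parse a written verdict table back into OutputRow values."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            rows.append(OutputRow.from_line(line))
    return rows
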