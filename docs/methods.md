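# Methods

## Model and assumptions

`srnascout` treats a small-RNA locus as a contiguous stack of read
alignments on one strand. Three phenomena complicate that picture and
drive the design:

* **Boundary fuzz.** Library preparation and degradation jitter read ends
  by a few nucleotides, and transcriptional read-through or overlapping
  loci chain distinct stacks into one merged cluster. The boundary
  optimizer assumes the true locus is the high-coverage core and that
  bridging/fringe reads are identifiable by low mean coverage weight.
* **Multi-mapping.** Many small-RNA genes (tRNAs, some miRNA and snoRNA
  families) exist in near-identical copies, so a large fraction of reads
  aligns to several loci. The model assumes a read's candidate origins
  appear as clusters sharing that read, and resolves them at cluster
  granularity — no fractional or probabilistic allocation.
* **Decoy transcription.** Fragments of mRNA and pseudogene transcripts
  masquerade as novel small RNAs; any cluster overlapping a
  protein-coding exon is vetoed rather than reported as novel.

The pipeline is fully deterministic: no stage draws random numbers, ties
are broken by fixed keys, and repeated runs produce byte-identical
output.

## Parameters

| flag | default | meaning |
|---|---|---|
| `number-hits` | 5 | alignments above which a read is a discarded repeat |
| `max_indel_len` / `min_flank_len` | 5 / 5 nt | CIGAR indel length cap and required aligned flank |
| `number-reads` | 5 | minimum alignments per cluster ("fewer than" drops) |
| `percent-cur` | 0.3 | fraction of lowest-weight reads provisionally removed; removal count is `floor(percent_cur · n_total)` |
| `cutoff` | 0.3 | boundary acceptance margin: ratio must exceed `1 + cutoff` |
| `ratio_orientation` | `as_written` | which way the coverage ratio is taken (see below) |
| `ov-with-largest` | 0.75 | max fraction of a smaller node's alignments shared with the component's largest node |
| `percent-uniq` | 0.5 | unique-read fraction that accepts a node outright |
| `unique-reads` | 2 | unique-read count fallback (strictly greater accepts) |
| `jaccard-index` | 0.3 | minimum best Jaccard score for annotation (strictly greater) |
| length window | 17–200 nt | admissible cluster length |

All comparisons are strict inequalities, exactly as the thresholds are
phrased; boundary cases (a cluster of exactly 5 reads, a Jaccard score of
exactly 0.3) are unit-tested.

## Numerical and procedural choices

* **Read weights.** `Rw = (Σᵢ cov(pᵢ))/n` over the cluster's own coverage
  profile; integer arithmetic until the final division, so oracle
  comparisons are exact. Ties in the weight ordering are broken by
  (start, end, read id), making the removal set a deterministic prefix.
* **Ratio orientation.** The acceptance test is implemented as printed:
  accept the refined H1 sub-cluster when `W(H0)/W(H1) > 1 + cutoff`,
  where each side's mean coverage is computed from its own read set over
  its own span (H0 sections span to gap midpoints). Because removing
  reads can only lower coverage, this direction accepts refinement when
  H1 *lost* substantial coverage over the section — on a uniform stack
  (ratio ≈ 1/(1−percent_cur) ≈ 1.43) it accepts the unchanged span, but
  on a bridged double locus it keeps the H0 section on the denser stack.
  The `inverted` orientation (`W(H1)/W(H0)`) is the direction that
  actually rewards coverage-dense refined spans and cleanly splits the
  planted two-stack fixture; both are first-class options and the choice
  is a single flag.
* **Fate of removed reads.** Reads provisionally removed during boundary
  optimization re-attach to the accepted sub-cluster they overlap most
  (ties to the leftmost), so expression counts reflect all supporting
  reads; the accepted sub-cluster's refined span is pinned and does not
  re-expand. Removed reads overlapping no accepted sub-cluster are
  dropped. Retained H0 sections keep all their original reads, with the
  reported span clipped to the section.
* **Edge rule.** Share fractions use alignment-record counts over
  `n_total` (a read with two alignments inside one node counts twice); a
  `count_read_ids` switch counts distinct ids instead. Edges require a
  strict majority (> 0.5) in at least one direction.
* **Largest node / representative.** Greatest `n_total`, ties by
  `n_unique`, then leftmost coordinate — deterministic and biased toward
  the best-supported locus.
* **Coding veto.** Protein-coding annotation is held at exon granularity,
  so intronic clusters are clean. Unannotated candidates overlapping a
  coding exon are rejected with reason `coding_overlap` rather than
  reported as novel; provisionally annotated clusters that fail the
  Jaccard cutoff face the same veto before the close-proximity call.
* **Hit counting.** The SAM `NH` tag is trusted when present; otherwise
  records sharing a read id are counted, which requires the aligner to
  have reported all hits. Hit counts are taken genome-wide before CIGAR
  filtering (`count_hits_after_filter` switches this).
* **Degenerate inputs.** A cluster whose H1 is empty (everything removed)
  or has no covered base is returned unchanged; zero-cluster runs write
  header-only tables; annotation records without `transcript_id` are
  skipped with a warning.

## Synthetic data

The fixture generator plants loci of the four canonical length classes —
miRNA-like 17–25 nt, piRNA-like 20–40 nt, tRNA-like 60–90 nt,
snoRNA-like 60–150 nt — on synthetic contigs and draws reads whose ends
are jittered ±2 nt around the planted boundaries. Multi-copy loci place
homologous copies 10 kb apart and emit every read once per copy under one
read id, producing genuine multi-mapped reads with correct `NH` tags.
Decoy loci transcribe two exons of a protein-coding model; noise loci
scatter a handful of reads below the cluster read filter.

The default study scenario uses 20 single-copy loci (five per class,
depths 150–350, lengths chosen with a 2-nt margin inside each class
range so jittered spans stay in range), two coding decoys at depth 150,
and five noise loci at depth 4 — about 5,300 alignments, small enough
that the full pipeline runs in seconds while exercising every stage. The
repetitive scenario plants one tRNA-like locus in three copies at depth
30.

What passing on this data shows — and what it does not: the generator
reproduces coverage stacking, boundary fuzz, homology-driven
multi-mapping, and decoy transcription, so recovery and
false-positive-control results speak to the pipeline's logic. It does not
model base composition, sequencing error, alignment ambiguity beyond
exact homologous copies, or the long-tailed expression and annotation
incompleteness of real libraries, so absolute sensitivity on real data is
not implied.

## Evaluation conventions

A planted locus with simulated depth > 5 counts as recovered when any
network group containing a non-rejected cluster overlaps any of its
copies (a family is credited if the group contains the origin); it is a
false negative otherwise. A non-rejected cluster whose group-deduplicated
count exceeds 5 and overlaps no planted locus is a false positive. RPM
normalization, when reported, divides the group-deduplicated count by
(retained aligned reads / 10⁶).

## Known limitations

* Boundary optimization is a single pass; nested or heavily overlapping
  loci inside one cluster may not be fully separated.
* Multi-node resolution is rule-based; an expectation–maximization
  reassignment of multi-mapped reads is out of scope.
* Smaller copies of a clique family are classified low-quality by the
  decision tree (they share everything with the largest node); the family
  is represented by its strongest locus plus the shared group id, and
  expression is deduplicated at group level.
* Spliced or gapped small-RNA models are not supported; clusters are
  contiguous intervals.
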