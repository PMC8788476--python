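# srnascout

Discovery, quantification, and classification of small noncoding RNAs
(17–200 nt) from aligned small-RNA sequencing reads.

Most small-RNA callers are tuned for short reads (17–35 nt) and miRNA
detection, which under-represents the mid-sized species — tRNA fragments,
snoRNAs, piRNAs, snRNAs — that deep, length-unrestricted small-RNA
libraries capture. `srnascout` takes an alignment file produced from such a
library and a small-RNA annotation in GTF, and reports every expressed
locus as **annotated**, **in close proximity to annotation**,
**unannotated** (novel), or **rejected** (low quality), with expression
counts that handle multi-mapped reads honestly.

## The method

Starting from SAM/BAM alignments (adapter trimming and alignment are
upstream; `bwa aln -q 5 -k 1 -l 17` keeping multi-mapped hits is the
recommended invocation), the pipeline runs five stages:

1. **Alignment filtering.** CIGAR strings may contain only indels of
   ≤ 5 nt flanked on both sides by ≥ 5 aligned bases. Reads are classed by
   genome-wide hit count: *unique* (1 alignment), *multi-mapped*
   (2 – `number-hits`, default 5, kept), *repeat* (more, discarded).
2. **Clustering.** Chain-overlapping alignments (≥ 1 shared base,
   half-open coordinates, same strand) merge into read clusters; clusters
   with fewer than `number-reads` (default 5) alignments are set aside.
3. **Boundary optimization.** Each read gets a weight
   `Rw = Σᵢ cov(pᵢ) / n` — its mean per-base coverage. The lowest-weight
   fraction (`percent-cur`, default 0.3) is provisionally removed; the
   remainder (H1) splits into sub-clusters at zero-coverage transitions,
   and the original cluster (H0) is sectioned at the gap midpoints. A
   refined sub-cluster is accepted where the coverage ratio
   `W(H0)/W(H1)` exceeds `1 + cutoff` (default 0.3); otherwise the H0
   section survives, and consecutive surviving sections re-merge. A
   `--ratio-orientation inverted` switch compares `W(H1)/W(H0)` instead,
   which is the direction that actually splits bridged double loci.
4. **Cluster network.** Clusters become nodes; an edge joins two nodes
   when > 50 % of either node's alignments belong to reads that also align
   in the other. Components are labelled *single*, *star* (satellite
   false positives around one true locus), *clique* (a multi-copy RNA
   family), or *other*. Expression of a family is counted once: the
   group-deduplicated count counts each distinct read id a single time
   across the component.
5. **Decision tree + annotation.** The largest node of each component is
   accepted outright; each smaller node must pass read-depth,
   shared-with-largest (`ov-with-largest`, 0.75), unique-fraction
   (`percent-uniq`, 0.5), shared-with-others (50 %), and unique-count
   (`unique-reads`, 2) rules or be rejected. Accepted nodes are scored
   against annotation with the Jaccard index (intersection / union of the
   base ranges); a best score above `jaccard-index` (0.3) annotates the
   cluster, a lower score within 17–200 nt and clear of protein-coding
   exons yields *close proximity*, and unannotated clusters face the same
   coding-exon and length vetoes.

## Worked example

Generate a synthetic study set (20 planted small-RNA loci across the four
length classes, two multi-exon protein-coding decoys, scattered noise) and
run the pipeline:

```sh
srnascout simulate --seed 7 --outdir demo/data
# 5320 alignments over 27 loci written to demo/data

srnascout run \
    --alignments demo/data/reads.sam \
    --small-rna-gtf demo/data/small_rna.gtf \
    --host-gtf demo/data/host.gtf \
    --outdir demo/out
# {"annotated": 20, "close_proximity": 0, "unannotated": 0, "rejected": 19}

srnascout evaluate --truth demo/data/truth.tsv --results demo/out
# {"tp": 20, "fn": 0, "fp": 0, "recall": 1.0, "precision": 1.0, "f1": 1.0}
```

All 20 planted loci are recovered and annotated; the 19 rejected rows are
the decoy transcription (reason `coding_overlap`) and sub-threshold noise
clusters (`low_reads`). The output tables are BED-compliant TSV
(0-based half-open, unlike the 1-based GTF input):

```
#chrom  start  end    name           score  strand  best_feature_biotype  best_jaccard
chrT1   998    1023   cluster_00001  350    +       miRNA                 0.8400
chrT1   5998   6023   cluster_00006  300    +       miRNA                 0.8400
```

`score` is the group-deduplicated read count (capped at 1000 for BED
compatibility); each row also carries total/unique/shared read counts, the
network group id, and the full candidate-annotation list. A
`compare-modes` subcommand runs the network route against the naive
baseline that simply discards all shared multi-mapped reads, which erases
multi-copy families entirely.

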