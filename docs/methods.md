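# Methods

## Problem setting and assumptions

The input is one FASTQ file per gene cluster, containing sense-oriented,
adapter-trimmed cDNA reads that have already been error-corrected
upstream. The method assumes (i) reads are full-length or near
full-length copies of their transcript, so a read's seed path spans its
isoform end to end; (ii) residual errors are rare (about 1 % per base in
the corrected regime) and unstructured; (iii) isoforms of a gene share
exons, so a joint graph over all reads of the cluster lets low-abundance
isoforms borrow evidence from shared regions. No reference genome,
annotation or alignment to an external sequence is used anywhere.

## Seeding

A *positional minimizer* (m, p) of read r is the lexicographically
smallest k-mer fully contained in a window of w consecutive nucleotides
(ties broken by leftmost position; k-mers containing N are ineligible;
consecutive windows electing the same occurrence contribute one entry).
The "fully contained" semantics matters: eligible k-mer starts lie in
[p, p + w − k], not [p, p + w). Minimizer pairs are all ordered pairs at
separation x_min–x_max nt. Each pair spans the inclusive interval
[p_i, p_j + k − 1]; its weight is span × support, where support counts
the *distinct* reads of the batch containing the same k-mer pair (a pair
occurring twice in one read still counts once). Per read, a
maximum-weight set of pairwise non-overlapping intervals — the read's
NOMPs — is found by the standard weighted-interval-scheduling dynamic
program over intervals sorted by end position (exact, O(n log n)).

Defaults: k = 9, w = 10, x_min = 14, x_max = 80. These match the seeding
regime of the error-correction stage this tool is designed to follow;
k = 9 on ~1 %-error reads keeps most minimizers intact, and the 14–80 nt
separation band yields seeds long enough to be locally unique yet short
enough to survive between errors. All four are CLI flags.

## Graph construction

Reads are inserted in file order. Consecutive NOMPs become vertices
joined by directed edges; a global source s and sink t bracket every
read, so each read spells an s→t path (stored explicitly and maintained
through all later mutations). A NOMP occurrence merges into an existing
vertex with the same k-mer pair only if, in this order:

1. **acyclicity** — the new edge from the read's previous vertex must not
   close a cycle (checked by reachability; a vertex already housing an
   occurrence of the same read is likewise refused, which handles exact
   repeats);
2. **span** — the occurrence's span must be within δ of the candidate
   vertex's spans; among several candidates the closest span wins;
3. **gap** — if the edge between the two vertices already exists, the new
   inter-NOMP gap must be within δ of the recorded gaps. This rule only
   applies to edges between NOMP vertices: the offset between a read's
   start and its first NOMP is 5′ raggedness, not transcript structure,
   so source edges are exempt.

Otherwise a fresh vertex is created. δ defaults to 3 nt: larger than the
residual indel noise of corrected reads, comfortably smaller than the
smallest exon the simulator generates (20 nt), so exon-scale differences
always split. Positions are 0-based, intervals inclusive, and the gap
l(e) = start(next) − end(prev) − 1 is never negative within one read.

## Bubble popping

Errors that survive correction perturb seeds and produce *bubbles*:
internally node-disjoint path pairs between a branching vertex s′ and a
re-joining vertex t′, each path supported end-to-end by at least one
read. Candidates are all (s′, t′) with out-degree(s′) > 1,
in-degree(t′) > 1, s′ before t′ in topological order, and ≥ 2 reads
traversing both. Verification follows the supporting reads and groups
them by identical internal vertex sequence; if two distinct groups share
an internal vertex the candidate is skipped (a smaller bubble exists
between those reads). Verified bubbles are processed smallest first
(fewest distinct internal vertices).

Per path, the supporting reads' subsequences between their s′ and t′
anchor coordinates are collapsed to a consensus. Two paths merge when the
semiglobal alignment of their consensuses (match +2, mismatch −2, gap
open 12, extension 1) has no contiguous mismatch/indel run longer than δ
*and* identity (matches / alignment columns, terminal gaps included —
between fixed anchors a length difference is a real indel) above α
(default 0.9). Bubbles with three or more paths are tested pairwise in
descending read support, re-forming the consensus after each merge.

A popped bubble is linearized: its internal vertices are ordered by mean
read-space distance from s′ (ties by vertex id), the bubble-path edges
are replaced by a single chain, and every affected read path is rewritten
onto the chain. Linearization never increases the edge count. Because a
vertex inside a bubble may also be reachable from outside it, the
implementation re-checks acyclicity after rewiring and rolls the mutation
back (recording the bubble as unpoppable) in the rare case the
distance ordering would close a cycle through an outside path.

Iterations repeat — skipping remembered unpoppable bubbles (invalidated
if a later pop touches their endpoints) and deferring bubbles that
overlap an already-modified one — until fewer than N (default 1)
previously unseen bubbles are detected, with a hard cap of 100
iterations. Clustered errors occasionally produce difference runs of
4–5 nt, or drop short-segment identity below α, so a handful of
low-support paths can survive popping; the end-merging stage below
absorbs them, which is why the pipeline's outputs are clean even when
the graph retains a few extra paths.

## Consensus calling

All consensus calls (bubble paths and isoform groups) use a
backbone-anchored majority vote: the member of median length is the
backbone, every other member is globally aligned to it with edlib, and
each backbone column keeps the majority base (backbone base on ties), is
deleted on a deletion majority, and majority insertions are spliced in
between columns. For near-identical inputs — which is what both call
sites see — this converges to the same answer a partial-order alignment
would give, deterministically and in linear time per member. A single
member is returned unchanged.

## Isoform extraction and end-variability merging

After popping, reads are partitioned by identical s→t path; each group
becomes one prediction with the consensus of its member reads. cDNA
3′/5′ variability (RNA degradation, variable priming) produces
predictions that are truncated copies of one another, so predictions are
merged shortest-into-longest: the shorter consensus must *fit inside*
the longer one. The containment fit is an infix alignment (edlib HW —
every base of the shorter sequence accounted for, the longer's terminal
overhangs free) satisfying three gates:

- no mismatch/indel run longer than δ;
- no 20-column window with more than δ differences — two unrelated
  stretches differ in roughly two thirds of their columns even though
  coincidental matches keep every individual run short, whereas residual
  consensus errors essentially never reach four differences within 20
  columns; 20 nt is the smallest exon scale the tool must keep apart;
- identity above α.

Containment (rather than a free-end alignment) is essential: a
score-optimal free-end alignment may shift the shorter sequence's
terminus into an unrelated region and thereby disguise an internal exon
difference as terminal overhang. The merge is idempotent; consensus
sequences of merged read sets are recomputed from the pooled reads.

Clusters larger than the batch size (default 1000 reads) are processed
batch-wise in file order and the per-batch predictions merged with the
same rule. Final predictions need ≥ X supporting reads (default 5);
lower-support predictions are written to a secondary output rather than
discarded. Poly-A runs longer than 12 A's within the last 100 nt of each
read are compressed to a single A (qualities in lockstep) before any
other processing.

## Simulator

One simulated cluster = one gene. A seeded random reference (default
800 nt; a user FASTA is accepted) is partitioned left-to-right into
exons with lengths drawn uniformly from {20, 50, 100, 200}, the
remainder forming the last exon. Each isoform includes each exon
independently with probability 0.5; candidates shorter than 100 nt,
duplicates, candidates within 20 nt of pairwise exon-level difference,
and perfect substrings of an already-accepted isoform are rejected and
resampled (substring isoforms confound best-match evaluation and are by
construction collapsed by end-variability merging, so they are excluded
from ground truth). Reads are full-length copies at per-isoform
abundances drawn from {8, 16, 32, 64}, with per-base errors applied at
the target rate in a 1:1:1 substitution:insertion:deletion mix and the
pooled reads shuffled; an optional poly-A tail can be appended. The
realized median per-read error matches the nominal rate to within one
percentage point (checked by test).

What the simulator does **not** emulate: ONT homopolymer-biased and
quality-correlated error profiles, truncated or chimeric reads, internal
priming artifacts, strand errors, or inter-gene contamination from
imperfect upstream clustering. Passing the simulated suites therefore
demonstrates the graph algorithm's correctness under idealized
full-length input, not end-to-end robustness on raw biological data.

## Evaluation

Each prediction is assigned its best-matching truth by semiglobal
alignment score; per truth, the highest-scoring assigned prediction is a
true positive and the remainder are false positives; unmatched truths
are false negatives. Precision = TP/(TP+FP), recall = TP/(TP+FN).
Identity is matches over columns of the *global* alignment, so
incomplete ends are penalized; completeness requires the semiglobal
alignment to cover at least 95 % of the truth's length. With zero
predictions, precision is reported as null and recall as 0.

## Problem sizes and numerical choices

The shipped completeness experiment runs 10 replicates per isoform count
n ∈ {3, 5, 8} on 800-nt references at 1 % error — about three minutes on
one CPU — and is shared between the test suite and the reproduction
script. Determinism is end-to-end: all randomness flows from
`numpy.random.default_rng` seeds, tie-breaks (window minimizers, WIS
backtracking, vertex ordering, merge order) are fixed, and two runs on
the same input and seed produce byte-identical output FASTQ regardless
of thread count (clusters are the unit of parallelism; their outputs are
concatenated in sorted order).

## Known limitations

- Isoforms differing only by SNPs (or by terminal stretches shorter than
  about δ) are collapsed into one prediction by design.
- A transcript that is a perfect substring of a longer co-clustered
  transcript cannot be reported separately.
- Vertex-merge decisions depend on read insertion order (file order), as
  does the paper-trail of bubble popping; results are deterministic for
  a fixed input order but may differ between orderings.
- The O(reads² × pairs) support-counting step dominates runtime on large
  clusters; batching bounds it but very large clusters are slow.
- The consensus engine assumes members are near-identical copies; it is
  not a general multiple-sequence aligner.
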