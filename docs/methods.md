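# Methods

## Problem and model

Spliced aligners disagree. Given the same RNA-Seq read set, two aligners
(or one aligner under two parameter sets) will map most reads identically
but differ on a minority — different splice calls, different genomic
locations, unique versus multi-mapped, mapped versus unmapped. Absent a
ground truth, `alncompare` measures the *relative reliability* of the two
results, not their absolute correctness: it asks which result a user
should trust more for the uniquely mapped reads that feed downstream
analysis.

The model treats each aligner's uniquely mapped reads (NH tag = 1) as its
*positive set* and its multi-mapped reads (NH >= 2) as its *negative
set*. Every multi-mapping is taken at face value as a true negative;
false negatives are deliberately not accounted for, because the goal is
to find false positives hiding in the positive set. For each read mapped
by at least one aligner, the joint outcome falls into exactly one of
eight scenarios:

| scenario | joint outcome | labels (A, B) |
|---|---|---|
| 1 | unique + unique, identical alignment | TP, TP |
| 2 | unique + unique, overlapping, both sound | TP, TP |
| 3 | unique + unique, overlapping, short splice anchor on >= 1 side | per-side rule |
| 4 | unique + unique, different locations | FP, FP |
| 5 | unique vs multi-mapped | FP (unique side), TN |
| 6 | unique vs unmapped/absent | TP, none |
| 7 | multi + multi | TN, TN |
| 8 | multi vs unmapped/absent | TN, none |

In scenarios 2/3 each side is labelled independently by the
**splice-anchor rule**: an un-spliced alignment, or a spliced alignment
whose shortest intron-flanking anchor exceeds the overhang threshold, is
TP; a spliced alignment anchored by at most `overhang_threshold` read
bases (default 2 nt) across an intron is FP — one or two bases reaching
over a gap are very weak evidence for a junction. Scenario 3 is reported
whenever at least one side is FP; the number is cosmetic, the labels
drive all statistics. Both sides can be FP in scenario 3 (two different
short-anchor splices) just as both are TP in scenario 2.

Per aligner the counts give

    specificity = TN / (TN + FP)            (true-negative rate)
    accuracy    = (TP + TN) / (TP + FP + TN)

with false negatives excluded from both by design.

## Inference

The two metrics are compared with a **paired percentile bootstrap**.
The resampling unit is the read: its `(label_A, label_B)` outcome pair is
drawn with replacement, preserving the within-read dependence that the
comparison is about (both labels come from the same read, so they are
strongly correlated; independent per-side resampling would overstate the
variance of the difference). Per replicate both sides' specificity and
accuracy are recomputed and the differences (A − B) recorded; the
confidence interval is the empirical (α/2, 1 − α/2) percentile interval
of the replicate differences. Defaults: 10,000 replicates, 95% level.
A difference is significant when its interval excludes zero. The
percentile method was chosen over BCa/normal approximations as the
simplest method consistent with a plain "bootstrap confidence interval";
the point estimates always come from the unresampled tally.

The verdict is joint: a side is *selected* only when **both** metrics
differ significantly in its favour; significance on one metric only is
reported as "mixed"; otherwise "no significant difference". Three or
more alignment results are compared by sequential pairwise runs (compare
two, then compare the selected result with the next); there is no
automatic n-way mode.

### Numerical choices

- Replicates in which a metric's denominator is zero (no TN and no FP
  drawn, for specificity) are dropped from that metric's percentile
  computation; the dropped count is logged and reported. With zero
  variance in the outcomes the interval degenerates to (0, 0), which
  contains zero, so self-comparisons are never significant.
- Reads with a `none` label on one side (scenarios 6/8) are resampled
  like any read and contribute to the mapped side's counts only, keeping
  replicate tallies consistent with the full-data tally definition.
- The bootstrap is a pure function of (outcomes, n_boot, level, seed);
  the default seed is a fixed documented constant
  (`metrics.DEFAULT_SEED`) so repeated runs agree unless the user
  chooses otherwise. Resampling is chunked (256 replicates at a time) to
  bound memory; chunking does not affect the stream of random draws.

## Input contract and parsing decisions

Inputs are SAM or BAM files **grouped by read name** (``samtools sort
-n``); only adjacency of identical names is required, not any particular
collation order. A read name reappearing after a different name raises a
sort-order error rather than silently splitting the read.

- **Read key.** QNAME for single-end data; when paired flags are set,
  mates are keyed `name/1` and `name/2` and treated as independent
  reads. The per-read logic is defined for single-end data; per-mate
  keying extends it without inventing fragment-level rules.
- **Coordinates** are 1-based inclusive throughout, as in SAM text.
- **Block decomposition.** Reference blocks are maximal runs of
  reference-consuming CIGAR operations (M, =, X, D) split only at N.
  Deletions extend a block; only N — which SAM reserves for introns —
  creates a splice gap. S/H/I/P consume no reference. An N at the
  leading or trailing reference-consuming edge of a CIGAR is rejected as
  malformed.
- **Uniqueness.** NH = 1 is unique, NH >= 2 multi-mapped. When NH is
  absent, the count of mapped non-supplementary records in the group
  stands in; when NH contradicts that count, a warning is logged and the
  count wins (the comparison can only see the records present).
  Supplementary records never enter the uniqueness count.
- **Identity and overlap.** Two unique alignments are *identical* when
  reference, strand and the block (start, end) lists agree — soft clips
  and insertions do not discriminate. They *overlap* when some block of
  one shares >= 1 reference base with some block of the other, on the
  same reference and strand; alignments sharing only an intron gap do
  not overlap. Opposite-strand placements at the same coordinates are
  "different locations" (scenario 4): a read cannot originate from both
  strands at once.
- **Absent vs unmapped.** A read missing from one file and a read
  present with the unmapped flag are the same condition ("this aligner
  failed to map the read") and flow into scenarios 6/8. Differing read
  universes produce a warning with counts so accidentally mismatched
  inputs are noticeable. Reads unmapped or absent on both sides carry no
  information and are skipped (counted in a diagnostic).
- **Stream joining.** Side B is indexed by read key, side A is walked in
  file order, then B-only reads follow in B's order. The result is
  deterministic and independent of the two files' relative name order,
  at the cost of holding side B's groups in memory.

## Synthetic data generator

The generator emulates what the comparison actually consumes: two
aligners' coordinate/CIGAR/flag-level views of one single-end short-read
set. Defaults: reads 40–51 nt (drawn per read), synthetic intron lengths
60–2000 bp, three 1-Mb references, and a scenario mix dominated by
concordant unique mappings (70% scenario 1, 5% each for 2 and 3, 4%
discordant, 6% unique-vs-multi, 4% unique-vs-unmapped, 4% multi-multi,
2% multi-vs-unmapped) — the regime in which two reasonable spliced
aligners mostly agree. Which side carries the unique/clean alignment in
asymmetric scenarios is randomised per read, so neither side is
systematically favoured. Unmapped outcomes are realised half as
unmapped-flag records and half as reads absent from the file.

Read sequences are arbitrary bases: classification never inspects base
identity, only coordinates, CIGARs, flags and NH tags, so no reference
FASTA is involved. This is a documented limitation — the generator
exercises the classification and inference machinery exhaustively, but
passing tests say nothing about alignment quality on real data (error
models, quality strings, expression structure and reference context are
all absent). One PRNG stream, seeded from the recipe, drives each file
pair; the truth table records the seed.

Three worked examples with fixed genomic coordinates are built in
(mouse-genome-sized headers): a 40-nt read mapped contiguously at
chr2:152,318,712–152,318,751 by one aligner but spliced as 1M257N39M
from 152,318,455 (a 1-base anchor across a 257-bp intron) by the other;
a 40-nt read placed uniquely at chr11:109,011,648 versus
chr7:110,059,825; and a 51-nt read reported at MT:7,465 plus a spliced
nuclear alignment spanning chr1:24,615,063–24,615,663 (NH = 2) by one
aligner but uniquely at MT:7,465 by the other. The nuclear alignment's
internal split (25M550N26M) is synthesised to fill the printed span;
the labels do not depend on it.

## Problem sizes used in the test and acceptance runs

Round-trip suites use 20 seeds × 500 reads; oracle-equivalence suites
use 50-read fixtures with a uniform scenario mix; the bootstrap
calibration uses 200 repetitions of 300 reads at 1,000 replicates,
checking that the 95% interval covers zero in 95 ± 4% of repetitions
when both sides share one generating distribution. These sizes give
stable statistics in seconds on one CPU.

## Known limitations

- Relative reliability only: a scenario-4 read is FP for *both* sides
  even though one may be correct; the method cannot tell which.
- Multi-mapped reads are always true negatives; a wrong multi-mapping is
  invisible.
- CRAM input, mate-aware fragment logic and n-way comparison are not
  implemented.
- Side B's read groups are held in memory during the join; very large
  BAMs with highly discordant name orders pay that memory cost.
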