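# alncompare

Which spliced-alignment result of your RNA-Seq data should you trust?
`alncompare` compares two alignment results of the **same read set** —
from two different aligners, or one aligner under two parameter sets —
and decides which one is more reliable, without needing a ground truth.
It is aimed at RNA-Seq analysts choosing an aligner/parameter
combination before quantification and differential-expression work,
where the uniquely mapped reads are what matters.

## Method

Each aligner's uniquely mapped reads (NH tag = 1) form its positive set
and its multi-mapped reads (NH ≥ 2) its negative set; multi-mappings
are always counted as true negatives (TN) and false negatives are
deliberately out of scope. Reading both name-grouped SAM/BAM files in
one pass, every read's joint outcome is classified into one of eight
scenarios — same unique alignment, overlapping unique alignments (with
a splice-anchor soundness rule), different unique locations, unique vs
multi-mapped, unique vs unmapped, multi vs multi, multi vs unmapped —
yielding per-aligner TP/FP/TN labels. A spliced alignment anchored by
≤ 2 read bases across an intron (CIGAR `N` gap) is called a false
positive (FP); an un-spliced alignment or one with longer anchors
overlapping it is a true positive (TP).

Per aligner:

    specificity = TN / (TN + FP)
    accuracy    = (TP + TN) / (TP + FP + TN)

Differences between the aligners are assessed with a paired percentile
bootstrap (default 10,000 resamples of reads, 95% interval); a side is
*selected* only when both metrics differ significantly in its favour.
See `docs/methods.md` for the full model, assumptions and numerical
choices.

## Worked example

The package ships three built-in example reads at fixed genomic
coordinates, one per discordance class — a read mapped contiguously by
one aligner but spliced with a 1-base anchor across a 257-bp intron by
the other; a read placed uniquely on two different chromosomes; and a
read reported multi-mapped by one aligner but uniquely by the other:

```python
from alncompare import builtin_worked_examples, write_pair
sam_a, sam_b, truth = builtin_worked_examples()
write_pair(sam_a, sam_b, "example")
```

```sh
alncompare --a example/aligner_a.sam --b example/aligner_b.sam \
           --label-a GSNAP-like --label-b TopHat2-like
```

prints

```
key	value
scenario_1	0
scenario_2	0
scenario_3	1
scenario_4	1
scenario_5	1
scenario_6	0
scenario_7	0
scenario_8	0
TP[GSNAP-like]	1
FP[GSNAP-like]	1
TN[GSNAP-like]	1
specificity[GSNAP-like]	0.500000
accuracy[GSNAP-like]	0.666667
TP[TopHat2-like]	0
FP[TopHat2-like]	3
TN[TopHat2-like]	0
specificity[TopHat2-like]	0.000000
accuracy[TopHat2-like]	0.000000
diff_specificity	0.500000
ci_specificity	0.000000,1.000000
significant_specificity	False
diff_accuracy	0.666667
ci_accuracy	0.000000,1.000000
significant_accuracy	False
n_boot	10000
level	0.95
seed	20150101
verdict	no significant difference
```

The short-anchor splice read lands in scenario 3 (TP for the contiguous
side, FP for the 1-base-anchor side), the cross-chromosome read in
scenario 4 (FP for both — each aligner missed the location the other
found), and the multi-vs-unique read in scenario 5 (TN for the
multi-mapping side, FP for the side that wrongly reported uniqueness).
Side A therefore scores specificity 1/(1+1) = 0.5 and accuracy
(1+1)/3 ≈ 0.667 versus 0.0 and 0.0 for side B — but with only three
reads the bootstrap intervals span zero, so no side is selected: the
verdict rule demands joint significance, which needs realistic read
counts (see the synthetic-mix tests).

Useful flags: `--n-boot`, `--level`, `--seed` (bootstrap), `--overhang`
(splice-anchor FP threshold, default 2 nt), `--scenario-tsv` (per-read
dump), `--format json`. Three or more alignment results: compare two,
then compare the winner with the third.

The `alncompare.simulate` module generates arbitrary synthetic file
pairs with per-read truth tables (`ScenarioMixSpec`, `generate`) for
testing and benchmarking.

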