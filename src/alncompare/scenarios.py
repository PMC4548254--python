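"""Eight-scenario joint classification of a read across two aligners.

Uniquely mapped reads form the positive set and multi-mapped reads the
negative set; every multi-mapping is taken as a true negative, and false
negatives are deliberately out of scope. For a read mapped by both
aligners the joint outcome falls into exactly one scenario:

==========  =========================================  ==================
scenario    joint outcome                              labels (a, b)
==========  =========================================  ==================
1           unique + unique, identical alignment       TP, TP
2           unique + unique, overlapping, both sound   TP, TP
3           unique + unique, overlapping, short-        per-side rule
            overhang splice on >=1 side
4           unique + unique, different locations       FP, FP
5           unique vs multi-mapped                     FP (unique), TN
6           unique vs unmapped/absent                  TP, none
7           multi-mapped + multi-mapped                TN, TN
8           multi-mapped vs unmapped/absent            TN, none
==========  =========================================  ==================

In scenarios 2/3 each side is labelled independently: a spliced
alignment whose shortest intron-flanking anchor is at most
``overhang_threshold`` read bases (default 2) is a likely misplaced
junction and is called FP; an un-spliced alignment or one with longer
anchors is called TP. Scenario 3 is reported when either side is FP,
scenario 2 when both are sound — the per-side labels, not the scenario
number, drive all downstream statistics.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Tuple

from .errors import AlncompareError
from .sam_model import (
    AlignmentRecord,
    MappingStatus,
    ReadMappingGroup,
    min_splice_overhang,
    reference_blocks,
)

logger = logging.getLogger(__name__)

DEFAULT_OVERHANG_THRESHOLD = 2


class Label(enum.Enum):
    """Per-aligner outcome label for one read."""

    TP = "TP"
    FP = "FP"
    TN = "TN"
    NONE = "none"


@dataclass(frozen=True)
class ScenarioCall:
    """Joint classification of one read across the two aligners."""

    read_key: str
    scenario: int
    label_a: Label
    label_b: Label

    def swapped(self) -> "ScenarioCall":
        """The same call with the two sides exchanged."""
        return ScenarioCall(self.read_key, self.scenario, self.label_b, self.label_a)


@dataclass
class ComparisonTally:
    """Aggregate TP/FP/TN counts per aligner plus per-read outcomes.

    ``per_read_outcomes`` keeps one ``(label_a, label_b)`` pair per read
    so the paired bootstrap can resample reads, not counts.
    """

    tp_a: int = 0
    fp_a: int = 0
    tn_a: int = 0
    tp_b: int = 0
    fp_b: int = 0
    tn_b: int = 0
    per_read_outcomes: list[Tuple[Label, Label]] = field(default_factory=list)
    scenario_counts: dict[int, int] = field(default_factory=dict)
    n_only_in_a: int = 0
    n_only_in_b: int = 0
    n_unmapped_both: int = 0

    def add(self, call: ScenarioCall) -> None:
        self.per_read_outcomes.append((call.label_a, call.label_b))
        self.scenario_counts[call.scenario] = (
            self.scenario_counts.get(call.scenario, 0) + 1
        )
        for label, side in ((call.label_a, "a"), (call.label_b, "b")):
            if label is Label.NONE:
                continue
            attr = f"{label.value.lower()}_{side}"
            setattr(self, attr, getattr(self, attr) + 1)

    @property
    def n_reads(self) -> int:
        return len(self.per_read_outcomes)


def same_alignment(rec_a: AlignmentRecord, rec_b: AlignmentRecord) -> bool:
    """True iff the two mapped records describe the identical alignment.

    Identity means same reference, same strand and the same reference
    block structure (block starts and ends; soft clips and insertions do
    not enter the comparison).
    """
    if rec_a.reference_name != rec_b.reference_name or rec_a.strand != rec_b.strand:
        return False
    blocks_a = [(b.start_1based, b.end_1based) for b in reference_blocks(rec_a)]
    blocks_b = [(b.start_1based, b.end_1based) for b in reference_blocks(rec_b)]
    return blocks_a == blocks_b


def overlapping(rec_a: AlignmentRecord, rec_b: AlignmentRecord) -> bool:
    """True iff the two alignments share >= 1 aligned reference base.

    Requires same reference and strand; overlap is tested block against
    block, so two alignments sharing only an intron gap do not count.
    """
    if rec_a.reference_name != rec_b.reference_name or rec_a.strand != rec_b.strand:
        return False
    blocks_b = reference_blocks(rec_b)
    return any(
        ba.overlaps(bb) for ba in reference_blocks(rec_a) for bb in blocks_b
    )


def splice_label(
    record: AlignmentRecord, overhang_threshold: int = DEFAULT_OVERHANG_THRESHOLD
) -> Label:
    """Label one unique alignment by the splice-junction overhang rule.

    An un-spliced alignment is TP. A spliced alignment is FP when its
    shortest intron-flanking anchor is ``overhang_threshold`` read bases
    or fewer (default 2): one or two bases reaching across an intron are
    very likely misplaced.
    """
    overhang = min_splice_overhang(record)
    if overhang is not None and overhang <= overhang_threshold:
        return Label.FP
    return Label.TP


def classify_pair(
    group_a: ReadMappingGroup,
    group_b: ReadMappingGroup,
    overhang_threshold: int = DEFAULT_OVERHANG_THRESHOLD,
) -> ScenarioCall:
    """Assign the read's joint scenario and per-aligner labels.

    Decision order for two unique mappings: identical alignment
    (scenario 1) before overlapping (2/3) before different locations
    (4). Opposite-strand mappings are "different locations", never
    overlapping. Raises if the read is unmapped on both sides — such
    reads carry no information and must be filtered by the caller.
    """
    if group_a.read_key != group_b.read_key:
        raise AlncompareError(
            f"read keys differ: {group_a.read_key!r} vs {group_b.read_key!r}"
        )
    key = group_a.read_key
    sa = group_a.status or MappingStatus.NOT_MAPPED
    sb = group_b.status or MappingStatus.NOT_MAPPED
    U, N, X = MappingStatus.UNIQUE, MappingStatus.NON_UNIQUE, MappingStatus.NOT_MAPPED

    if sa is X and sb is X:
        raise AlncompareError(f"read {key!r} unmapped on both sides")

    if sa is U and sb is U:
        rec_a = group_a.primary_record
        rec_b = group_b.primary_record
        assert rec_a is not None and rec_b is not None
        if same_alignment(rec_a, rec_b):
            return ScenarioCall(key, 1, Label.TP, Label.TP)
        if overlapping(rec_a, rec_b):
            la = splice_label(rec_a, overhang_threshold)
            lb = splice_label(rec_b, overhang_threshold)
            scenario = 3 if Label.FP in (la, lb) else 2
            return ScenarioCall(key, scenario, la, lb)
        return ScenarioCall(key, 4, Label.FP, Label.FP)
    if sa is U and sb is N:
        return ScenarioCall(key, 5, Label.FP, Label.TN)
    if sa is N and sb is U:
        return ScenarioCall(key, 5, Label.TN, Label.FP)
    if sa is U and sb is X:
        return ScenarioCall(key, 6, Label.TP, Label.NONE)
    if sa is X and sb is U:
        return ScenarioCall(key, 6, Label.NONE, Label.TP)
    if sa is N and sb is N:
        return ScenarioCall(key, 7, Label.TN, Label.TN)
    if sa is N and sb is X:
        return ScenarioCall(key, 8, Label.TN, Label.NONE)
    # sa is X and sb is N
    return ScenarioCall(key, 8, Label.NONE, Label.TN)


def compare_streams(
    groups_a: Iterable[ReadMappingGroup],
    groups_b: Iterable[ReadMappingGroup],
    overhang_threshold: int = DEFAULT_OVERHANG_THRESHOLD,
) -> Tuple[list[ScenarioCall], ComparisonTally]:
    """Classify every read present in either input.

    The two inputs need not list reads in the same order: side B is
    indexed by read key and side A is walked in file order, then B-only
    reads follow in B's order, so the output is deterministic and
    order-independent. Reads present in only one file are classified
    (scenarios 6/8 treat absence as failure to map) and their count is
    reported as a warning; reads unmapped or absent on both sides are
    skipped and counted in the tally's diagnostic.
    """
    calls: list[ScenarioCall] = []
    tally = ComparisonTally()

    b_index: dict[str, ReadMappingGroup] = {}
    for group in groups_b:
        if group.read_key in b_index:
            raise AlncompareError(f"duplicate read key {group.read_key!r} in side B")
        b_index[group.read_key] = group

    seen_a: set[str] = set()
    for ga in groups_a:
        if ga.read_key in seen_a:
            raise AlncompareError(f"duplicate read key {ga.read_key!r} in side A")
        seen_a.add(ga.read_key)
        gb = b_index.pop(ga.read_key, None)
        if gb is None:
            tally.n_only_in_a += 1
            gb = ReadMappingGroup(ga.read_key, [], MappingStatus.NOT_MAPPED)
        if (
            (ga.status or MappingStatus.NOT_MAPPED) is MappingStatus.NOT_MAPPED
            and gb.status is MappingStatus.NOT_MAPPED
        ):
            tally.n_unmapped_both += 1
            continue
        call = classify_pair(ga, gb, overhang_threshold)
        calls.append(call)
        tally.add(call)

    for gb in b_index.values():  # reads present only in side B, in B's order
        tally.n_only_in_b += 1
        if (gb.status or MappingStatus.NOT_MAPPED) is MappingStatus.NOT_MAPPED:
            tally.n_unmapped_both += 1
            continue
        ga = ReadMappingGroup(gb.read_key, [], MappingStatus.NOT_MAPPED)
        call = classify_pair(ga, gb, overhang_threshold)
        calls.append(call)
        tally.add(call)

    if tally.n_only_in_a or tally.n_only_in_b:
        logger.warning(
            "read universes differ: %d reads only in side A, %d only in side B "
            "(classified as unmapped on the missing side)",
            tally.n_only_in_a,
            tally.n_only_in_b,
        )
    return calls, tally


def write_scenario_tsv(calls: Iterable[ScenarioCall], path) -> None:
    """Dump per-read calls as TSV: read_key, scenario, label_a, label_b."""
    with open(path, "w") as fh:
        fh.write("read_key\tscenario\tlabel_a\tlabel_b\n")
        for call in calls:
            fh.write(
                f"{call.read_key}\t{call.scenario}\t"
                f"{call.label_a.value}\t{call.label_b.value}\n"
            )
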