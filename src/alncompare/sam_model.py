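"""Domain model for name-grouped SAM/BAM alignment records.

This module turns SAM/BAM files into the objects the comparison logic
works with: one :class:`ReadMappingGroup` per read, a resolved
:class:`MappingStatus` (unique / non-unique / not mapped), and the
reference-coordinate block structure of each alignment derived from its
CIGAR string. Blocks are split only at ``N`` operations (introns in
spliced RNA-Seq alignments), which is the substrate for the
splice-junction overhang rule used downstream.

Coordinates are 1-based inclusive throughout, matching SAM text.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Tuple, Union

import pysam

from .errors import SamParseError, SortOrderError

logger = logging.getLogger(__name__)

#: CIGAR operation characters indexed by the integer codes pysam uses.
CIGAR_OPS = "MIDNSHP=X"

#: Operations that consume reference bases.
_REF_CONSUMING = frozenset("MDN=X")
#: Operations that consume read (query) bases.
_READ_CONSUMING = frozenset("MIS=X")
#: Operations that place read bases on the reference (aligned bases).
_ALIGNED = frozenset("M=X")


class MappingStatus(enum.Enum):
    """Resolved mapping status of one read under one aligner."""

    UNIQUE = "unique"
    NON_UNIQUE = "non_unique"
    NOT_MAPPED = "not_mapped"


@dataclass(frozen=True)
class AlignmentRecord:
    """One SAM line, reduced to the fields the comparison needs.

    ``start_1based`` is the leftmost reference position (1-based, as
    printed in SAM text). ``cigar`` is an ordered list of
    ``(operation_char, length)`` pairs. ``nh`` is the value of the
    optional ``NH:i`` tag (number of reported hits) or ``None``.
    """

    read_key: str
    is_mapped: bool
    reference_name: Optional[str] = None
    strand: Optional[str] = None
    start_1based: Optional[int] = None
    cigar: Tuple[Tuple[str, int], ...] = ()
    nh: Optional[int] = None
    is_secondary: bool = False
    is_supplementary: bool = False

    def __post_init__(self) -> None:
        if self.is_mapped:
            if self.start_1based is None or self.start_1based < 1:
                raise SamParseError(
                    f"mapped record {self.read_key!r} needs a 1-based start >= 1"
                )
            if not self.cigar:
                raise SamParseError(
                    f"mapped record {self.read_key!r} has an empty CIGAR"
                )
            for op, length in self.cigar:
                if op not in CIGAR_OPS:
                    raise SamParseError(f"unknown CIGAR operation {op!r}")
                if length < 1:
                    raise SamParseError(f"non-positive CIGAR length {length}")
            if self.strand not in ("+", "-"):
                raise SamParseError(
                    f"mapped record {self.read_key!r} needs strand '+' or '-'"
                )
        if self.nh is not None and self.nh < 1:
            raise SamParseError(f"NH tag must be >= 1, got {self.nh}")

    @property
    def read_length(self) -> int:
        """Read length implied by the CIGAR (read-consuming ops)."""
        return sum(n for op, n in self.cigar if op in _READ_CONSUMING)


@dataclass(frozen=True)
class ReferenceBlock:
    """A maximal run of reference-consuming CIGAR ops between N gaps.

    ``aligned_read_bases`` counts the read bases actually placed on the
    reference within the block (M/=/X); deletions extend the block's
    reference span without contributing read bases.
    """

    start_1based: int
    end_1based: int
    aligned_read_bases: int

    def __post_init__(self) -> None:
        if self.end_1based < self.start_1based:
            raise ValueError("block end precedes start")

    def overlaps(self, other: "ReferenceBlock") -> bool:
        """True if the two blocks share at least one reference base."""
        return (
            self.start_1based <= other.end_1based
            and other.start_1based <= self.end_1based
        )


@dataclass
class ReadMappingGroup:
    """All records one aligner reported for one read key."""

    read_key: str
    records: list[AlignmentRecord] = field(default_factory=list)
    status: Optional[MappingStatus] = None

    @property
    def mapped_records(self) -> list[AlignmentRecord]:
        return [r for r in self.records if r.is_mapped]

    @property
    def primary_record(self) -> Optional[AlignmentRecord]:
        """The primary (non-secondary, non-supplementary) mapped record."""
        for rec in self.records:
            if rec.is_mapped and not rec.is_secondary and not rec.is_supplementary:
                return rec
        return None


def resolve_status(group: ReadMappingGroup) -> MappingStatus:
    """Resolve unique / non-unique / unmapped for one read group.

    Uniqueness follows the ``NH`` tag convention: NH = 1 marks a unique
    mapping, NH >= 2 an ambiguous (multi-) mapping. When NH is absent the
    number of mapped non-supplementary records stands in. If NH disagrees
    with the record count, a warning is logged and the record count wins —
    the records actually present are what the comparison can see.
    """
    mapped = [r for r in group.records if r.is_mapped and not r.is_supplementary]
    if not mapped:
        return MappingStatus.NOT_MAPPED
    primary = group.primary_record or mapped[0]
    count_status = (
        MappingStatus.UNIQUE if len(mapped) == 1 else MappingStatus.NON_UNIQUE
    )
    if primary.nh is None:
        return count_status
    if primary.nh != len(mapped):
        logger.warning(
            "read %s: NH=%d but %d mapped records present; using record count",
            group.read_key,
            primary.nh,
            len(mapped),
        )
        return count_status
    return MappingStatus.UNIQUE if primary.nh == 1 else MappingStatus.NON_UNIQUE


def reference_blocks(record: AlignmentRecord) -> list[ReferenceBlock]:
    """Decompose a mapped record's CIGAR into reference blocks.

    Blocks are maximal runs of reference-consuming operations (M, =, X,
    D) split only at N (intron) gaps; S/H/I/P consume no reference and
    never split a block. Coordinates are 1-based inclusive.
    """
    if not record.is_mapped:
        raise SamParseError("cannot take reference blocks of an unmapped record")
    # N at the leading or trailing reference-consuming edge is malformed:
    # an intron gap must be flanked by aligned sequence on both sides.
    ref_ops = [op for op, _ in record.cigar if op in _REF_CONSUMING]
    if ref_ops and (ref_ops[0] == "N" or ref_ops[-1] == "N"):
        raise SamParseError(
            f"record {record.read_key!r}: N operation at CIGAR start or end"
        )

    blocks: list[ReferenceBlock] = []
    pos = record.start_1based  # next unconsumed reference position
    block_start: Optional[int] = None
    aligned = 0
    for op, length in record.cigar:
        if op == "N":
            if block_start is not None:
                blocks.append(ReferenceBlock(block_start, pos - 1, aligned))
                block_start, aligned = None, 0
            pos += length
        elif op in _REF_CONSUMING:
            if block_start is None:
                block_start = pos
            pos += length
            if op in _ALIGNED:
                aligned += length
        # S/H/I/P: no reference consumption, block unaffected
    if block_start is not None:
        blocks.append(ReferenceBlock(block_start, pos - 1, aligned))
    if not blocks:
        raise SamParseError(
            f"record {record.read_key!r}: CIGAR consumes no reference"
        )
    return blocks


def min_splice_overhang(record: AlignmentRecord) -> Optional[int]:
    """Minimum aligned read bases in any block flanking an intron gap.

    Returns ``None`` for un-spliced alignments (no N operation). For a
    spliced alignment, every block borders at least one N gap except
    none — with k gaps there are k+1 blocks and all of them flank a gap —
    so this is the minimum ``aligned_read_bases`` over all blocks.
    """
    if not any(op == "N" for op, _ in record.cigar):
        return None
    blocks = reference_blocks(record)
    return min(b.aligned_read_bases for b in blocks)


# ---------------------------------------------------------------------------
# File reading


def _record_from_segment(
    seg: pysam.AlignedSegment, sam: pysam.AlignmentFile
) -> AlignmentRecord:
    """Convert one pysam segment to the domain record."""
    key = seg.query_name or ""
    if seg.is_paired:
        # mates are keyed separately: per-read logic, no fragment rules
        key += "/2" if seg.is_read2 else "/1"
    if seg.is_unmapped:
        return AlignmentRecord(read_key=key, is_mapped=False,
                               nh=_nh_of(seg),
                               is_secondary=seg.is_secondary,
                               is_supplementary=seg.is_supplementary)
    if seg.cigartuples is None:
        raise SamParseError(f"mapped record {key!r} without a CIGAR")
    cigar = tuple((CIGAR_OPS[op], length) for op, length in seg.cigartuples)
    return AlignmentRecord(
        read_key=key,
        is_mapped=True,
        reference_name=sam.get_reference_name(seg.reference_id),
        strand="-" if seg.is_reverse else "+",
        start_1based=seg.reference_start + 1,
        cigar=cigar,
        nh=_nh_of(seg),
        is_secondary=seg.is_secondary,
        is_supplementary=seg.is_supplementary,
    )


def _nh_of(seg: pysam.AlignedSegment) -> Optional[int]:
    try:
        return int(seg.get_tag("NH"))
    except KeyError:
        return None


def stream_read_groups(
    path: Union[str, Path],
) -> Iterator[ReadMappingGroup]:
    """Stream one :class:`ReadMappingGroup` per read from a SAM/BAM file.

    The file must be grouped by read name (``samtools sort -n`` order or
    any order in which all records of a read are adjacent). A
    :class:`SortOrderError` is raised if a read key reappears after a
    different key — the single-pass grouping contract would otherwise
    silently split reads.

    Each yielded group has its ``status`` resolved.
    """
    path = str(path)
    with pysam.AlignmentFile(path, check_sq=False) as sam:
        seen: set[str] = set()
        current: Optional[ReadMappingGroup] = None
        for seg in sam:
            try:
                rec = _record_from_segment(seg, sam)
            except SamParseError:
                raise
            except Exception as exc:  # pragma: no cover - pysam internals
                raise SamParseError(f"malformed record in {path}: {exc}") from exc
            if current is not None and rec.read_key == current.read_key:
                current.records.append(rec)
                continue
            if rec.read_key in seen:
                raise SortOrderError(
                    f"{path}: read {rec.read_key!r} reappears after other "
                    "reads; input must be grouped by read name "
                    "(samtools sort -n)"
                )
            if current is not None:
                current.status = resolve_status(current)
                yield current
            seen.add(rec.read_key)
            current = ReadMappingGroup(read_key=rec.read_key, records=[rec])
        if current is not None:
            current.status = resolve_status(current)
            yield current


def group_from_records(
    read_key: str, records: Iterable[AlignmentRecord]
) -> ReadMappingGroup:
    """Build a status-resolved group directly from records (test helper)."""
    group = ReadMappingGroup(read_key=read_key, records=list(records))
    group.status = resolve_status(group)
    return group
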