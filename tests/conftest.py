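"""Shared fixtures: SAM writing helpers and a brute-force oracle.

The oracle re-implements the read-pair classification directly from raw
SAM fields (flag bits, CIGAR strings, NH tags) without touching the
package's domain model, so streaming/classifier bugs cannot cancel out.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pysam
import pytest

from alncompare import AlignmentRecord

_CIG = re.compile(r"(\d+)([MIDNSHP=X])")


# ---------------------------------------------------------------------------
# Record construction helper

def mk_rec(
    key: str = "r1",
    ref: Optional[str] = "chr1",
    start: Optional[int] = 100,
    cigar: str = "40M",
    strand: str = "+",
    nh: Optional[int] = 1,
    mapped: bool = True,
    secondary: bool = False,
    supplementary: bool = False,
) -> AlignmentRecord:
    if not mapped:
        return AlignmentRecord(read_key=key, is_mapped=False, nh=nh)
    parsed = tuple(
        (m.group(2), int(m.group(1))) for m in _CIG.finditer(cigar)
    )
    return AlignmentRecord(
        read_key=key,
        is_mapped=True,
        reference_name=ref,
        strand=strand,
        start_1based=start,
        cigar=parsed,
        nh=nh,
        is_secondary=secondary,
        is_supplementary=supplementary,
    )


# ---------------------------------------------------------------------------
# Raw SAM text helpers

def write_sam(path: Path, body_lines: List[str],
              refs: Dict[str, int] | None = None) -> Path:
    refs = refs or {"chr1": 1_000_000, "chr2": 1_000_000}
    header = ["@HD\tVN:1.6\tSO:queryname"]
    header += [f"@SQ\tSN:{n}\tLN:{l}" for n, l in refs.items()]
    path.write_text("\n".join(header + body_lines) + "\n")
    return path


def sam_line(qname: str, flag: int = 0, rname: str = "chr1", pos: int = 100,
             cigar: str = "40M", seq_len: int = 40,
             nh: Optional[int] = 1) -> str:
    seq = "A" * seq_len if seq_len else "*"
    fields = [qname, str(flag), rname, str(pos), "60" if not flag & 4 else "0",
              cigar, "*", "0", "0", seq, "*"]
    if nh is not None:
        fields.append(f"NH:i:{nh}")
    return "\t".join(fields)


@pytest.fixture
def sam_pair_writer(tmp_path):
    """Write two SAM texts to disk, return the two paths."""

    def _write(sam_a: str, sam_b: str) -> Tuple[Path, Path]:
        pa = tmp_path / "a.sam"
        pb = tmp_path / "b.sam"
        pa.write_text(sam_a)
        pb.write_text(sam_b)
        return pa, pb

    return _write


# ---------------------------------------------------------------------------
# Brute-force oracle

RawRec = Tuple[int, Optional[str], int, Optional[str], Optional[int]]
# (flag, rname, pos_1based, cigarstring, nh)


def _load_raw(path) -> Dict[str, List[RawRec]]:
    out: Dict[str, List[RawRec]] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for seg in fh:
            nh = dict(seg.get_tags()).get("NH")
            rname = (
                None if seg.is_unmapped
                else fh.get_reference_name(seg.reference_id)
            )
            out.setdefault(seg.query_name, []).append(
                (seg.flag, rname, seg.reference_start + 1,
                 seg.cigarstring, nh)
            )
    return out


def _raw_blocks(pos: int, cigar: str) -> List[Tuple[int, int, int]]:
    blocks: List[Tuple[int, int, int]] = []
    start, aligned, p = None, 0, pos
    for m in _CIG.finditer(cigar):
        n, op = int(m.group(1)), m.group(2)
        if op == "N":
            if start is not None:
                blocks.append((start, p - 1, aligned))
                start, aligned = None, 0
            p += n
        elif op in "MD=X":
            if start is None:
                start = p
            p += n
            if op in "M=X":
                aligned += n
    if start is not None:
        blocks.append((start, p - 1, aligned))
    return blocks


def _raw_status(recs: List[RawRec]) -> str:
    mapped = [r for r in recs if not r[0] & 4 and not r[0] & 2048]
    if not mapped:
        return "unmapped"
    nh = next((r[4] for r in mapped if not r[0] & 256), mapped[0][4])
    if nh is not None and nh == len(mapped):
        return "unique" if nh == 1 else "multi"
    return "unique" if len(mapped) == 1 else "multi"


def _raw_primary(recs: List[RawRec]) -> RawRec:
    for r in recs:
        if not r[0] & 4 and not r[0] & 256 and not r[0] & 2048:
            return r
    raise AssertionError("no primary mapped record")


def _raw_splice_label(rec: RawRec, thr: int) -> str:
    blocks = _raw_blocks(rec[2], rec[3])
    if len(blocks) == 1:
        return "TP"
    return "FP" if min(b[2] for b in blocks) <= thr else "TP"


def oracle_classify(recs_a: Optional[List[RawRec]],
                    recs_b: Optional[List[RawRec]],
                    thr: int = 2) -> Optional[Tuple[int, str, str]]:
    """Literal decision-table classification of one read; None = skip."""
    sa = _raw_status(recs_a) if recs_a else "unmapped"
    sb = _raw_status(recs_b) if recs_b else "unmapped"
    if sa == "unmapped" and sb == "unmapped":
        return None
    if sa == "unique" and sb == "unique":
        ra, rb = _raw_primary(recs_a), _raw_primary(recs_b)
        same_loc = ra[1] == rb[1] and (ra[0] & 16) == (rb[0] & 16)
        ba, bb = _raw_blocks(ra[2], ra[3]), _raw_blocks(rb[2], rb[3])
        if same_loc and [x[:2] for x in ba] == [x[:2] for x in bb]:
            return (1, "TP", "TP")
        overlap = same_loc and any(
            u[0] <= v[1] and v[0] <= u[1] for u in ba for v in bb
        )
        if overlap:
            la, lb = _raw_splice_label(ra, thr), _raw_splice_label(rb, thr)
            return (3 if "FP" in (la, lb) else 2, la, lb)
        return (4, "FP", "FP")
    if sa == "unique" and sb == "multi":
        return (5, "FP", "TN")
    if sa == "multi" and sb == "unique":
        return (5, "TN", "FP")
    if sa == "unique":
        return (6, "TP", "none")
    if sb == "unique":
        return (6, "none", "TP")
    if sa == "multi" and sb == "multi":
        return (7, "TN", "TN")
    if sa == "multi":
        return (8, "TN", "none")
    return (8, "none", "TN")


def oracle_compare(path_a, path_b, thr: int = 2) -> Dict[str, Tuple[int, str, str]]:
    """Classify every read of a file pair with the brute-force oracle."""
    raw_a, raw_b = _load_raw(path_a), _load_raw(path_b)
    out: Dict[str, Tuple[int, str, str]] = {}
    for key in set(raw_a) | set(raw_b):
        res = oracle_classify(raw_a.get(key), raw_b.get(key), thr)
        if res is not None:
            out[key] = res
    return out
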