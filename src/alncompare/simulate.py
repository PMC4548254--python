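"""Synthetic paired SAM fixtures with known per-read scenario truth.

Two aligners' views of the same single-end short-read set are
synthesised directly at the coordinate/CIGAR/flag level: classification
never inspects base identity, so read sequences are arbitrary bases and
no reference FASTA is involved. The generator emits, per requested
read, a pair of record groups satisfying the defining geometry of a
chosen scenario — identical unique mappings, overlapping unique
mappings with or without a short-anchor splice, discordant unique
mappings, unique-versus-multimapped, unique-versus-unmapped, and the
multimapped counterparts — together with a truth table of the expected
scenario and per-side labels.

Three worked examples with fixed genomic coordinates are built in:
a 40-nt read mapped contiguously by one aligner but with a 1-base
splice anchor across a 257-bp intron by the other; a 40-nt read placed
uniquely on two different chromosomes; and a 51-nt read reported
multimapped (mitochondrial plus a spliced nuclear hit) by one aligner
but uniquely mitochondrial by the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .errors import GeometryError
from .scenarios import ComparisonTally, Label, ScenarioCall

#: Default read-length range (nt), matching typical single-end short reads.
READ_LENGTH_RANGE = (40, 51)

#: Default synthetic intron length range (bp).
INTRON_RANGE = (60, 2000)

#: Default scenario mix: mostly concordant unique mappings, with modest
#: fractions of every discordance class.
DEFAULT_PROPORTIONS: Dict[int, float] = {
    1: 0.70,
    2: 0.05,
    3: 0.05,
    4: 0.04,
    5: 0.06,
    6: 0.04,
    7: 0.04,
    8: 0.02,
}

DEFAULT_REFERENCES: Dict[str, int] = {
    "chr1": 1_000_000,
    "chr2": 1_000_000,
    "chr3": 1_000_000,
}

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ScenarioMixSpec:
    """Recipe for one synthetic file pair."""

    n_reads: int = 500
    proportions: Dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    read_length: Optional[int] = None  # None: draw per read from 40-51
    references: Dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_REFERENCES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"scenario proportions sum to {total}, not 1")
        if any(s not in range(1, 9) for s in self.proportions):
            raise ValueError("scenario keys must be in 1..8")


@dataclass
class TruthTable:
    """Expected per-read calls for a generated file pair."""

    rows: List[Tuple[str, int, Label, Label]] = field(default_factory=list)
    seed: Optional[int] = None

    def expected_tally(self) -> ComparisonTally:
        tally = ComparisonTally()
        for key, scenario, la, lb in self.rows:
            tally.add(ScenarioCall(key, scenario, la, lb))
        return tally

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("read_key\tscenario\tlabel_a\tlabel_b\n")
            for key, scenario, la, lb in self.rows:
                fh.write(f"{key}\t{scenario}\t{la.value}\t{lb.value}\n")


@dataclass
class _Rec:
    """One SAM line under construction."""

    qname: str
    flag: int = 0
    rname: str = "*"
    pos: int = 0
    cigar: str = "*"
    seq_len: int = 0
    nh: Optional[int] = None

    def to_sam(self, rng: np.random.Generator) -> str:
        seq = "".join(rng.choice(_BASES, size=self.seq_len)) if self.seq_len else "*"
        mapq = 0 if self.flag & 4 else 60
        fields = [
            self.qname,
            str(self.flag),
            self.rname,
            str(self.pos),
            str(mapq),
            self.cigar,
            "*",
            "0",
            "0",
            seq,
            "*",
        ]
        if self.nh is not None:
            fields.append(f"NH:i:{self.nh}")
        return "\t".join(fields)


def _cigar_read_len(cigar: str) -> int:
    out, num = 0, ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if ch in "MIS=X":
                out += int(num)
            num = ""
    return out


def _sam_text(records: List[_Rec], references: Dict[str, int],
              rng: np.random.Generator) -> str:
    lines = ["@HD\tVN:1.6\tSO:queryname"]
    lines += [f"@SQ\tSN:{name}\tLN:{length}" for name, length in references.items()]
    lines += [rec.to_sam(rng) for rec in records]
    return "\n".join(lines) + "\n"


class _ReadBuilder:
    """Synthesises the record pair for one read of a given scenario."""

    def __init__(self, spec: ScenarioMixSpec, rng: np.random.Generator) -> None:
        self.spec = spec
        self.rng = rng

    def _length(self) -> int:
        if self.spec.read_length is not None:
            return self.spec.read_length
        return int(self.rng.integers(READ_LENGTH_RANGE[0], READ_LENGTH_RANGE[1] + 1))

    def _pick_ref(self, span: int, exclude: Optional[str] = None) -> Tuple[str, int]:
        """A reference and start position that fit ``span`` bases."""
        candidates = [
            (name, length)
            for name, length in self.spec.references.items()
            if length >= span + 1 and name != exclude
        ]
        if not candidates:
            raise GeometryError(
                f"no reference of length >= {span + 1} available"
                + (f" (excluding {exclude})" if exclude else "")
            )
        name, length = candidates[int(self.rng.integers(len(candidates)))]
        pos = int(self.rng.integers(1, length - span + 1))
        return name, pos

    def _intron(self) -> int:
        return int(self.rng.integers(INTRON_RANGE[0], INTRON_RANGE[1] + 1))

    def _unique(self, qname: str, rname: str, pos: int, cigar: str,
                reverse: bool = False) -> _Rec:
        return _Rec(qname, 16 if reverse else 0, rname, pos, cigar,
                    _cigar_read_len(cigar), nh=1)

    def _multi_group(self, qname: str) -> List[_Rec]:
        """Two-location multimapped group, NH:i:2, second record secondary."""
        L = self._length()
        r1, p1 = self._pick_ref(L)
        r2, p2 = self._pick_ref(L)
        while r2 == r1 and abs(p2 - p1) < 2 * L:
            r2, p2 = self._pick_ref(L)
        rec1 = _Rec(qname, 0, r1, p1, f"{L}M", L, nh=2)
        rec2 = _Rec(qname, 256, r2, p2, f"{L}M", 0, nh=2)  # secondary: SEQ '*'
        return [rec1, rec2]

    def _unmapped(self, qname: str) -> List[_Rec]:
        """Unmapped-flag record, or absent from the file entirely."""
        if self.rng.random() < 0.5:
            return [_Rec(qname, 4, "*", 0, "*", self._length())]
        return []

    def build(self, qname: str, scenario: int
              ) -> Tuple[List[_Rec], List[_Rec], Label, Label]:
        fn = getattr(self, f"_s{scenario}")
        return fn(qname)

    # -- scenario geometries ------------------------------------------------

    def _s1(self, q: str):
        L = self._length()
        if self.rng.random() < 0.25:
            # identical spliced alignment, long anchors on both sides
            k = int(self.rng.integers(3, L - 2))
            gap = self._intron()
            ref, pos = self._pick_ref(L + gap)
            cigar = f"{k}M{gap}N{L - k}M"
        elif self.rng.random() < 0.2:
            clip = int(self.rng.integers(1, 6))
            ref, pos = self._pick_ref(L)
            cigar = f"{clip}S{L - clip}M"
        else:
            ref, pos = self._pick_ref(L)
            cigar = f"{L}M"
        rev = bool(self.rng.random() < 0.5)
        a = [self._unique(q, ref, pos, cigar, rev)]
        b = [self._unique(q, ref, pos, cigar, rev)]
        return a, b, Label.TP, Label.TP

    def _s2(self, q: str):
        # overlapping unique mappings, both sound: one contiguous, one
        # spliced with anchors >= 3 read bases
        L = self._length()
        k = int(self.rng.integers(3, L - 2))
        gap = self._intron()
        ref, pos = self._pick_ref(L + gap)
        a = [self._unique(q, ref, pos, f"{L}M")]
        b = [self._unique(q, ref, pos, f"{k}M{gap}N{L - k}M")]
        if self.rng.random() < 0.5:
            a, b = b, a
        return a, b, Label.TP, Label.TP

    def _s3(self, q: str):
        # overlapping unique mappings with a 1-2 nt splice anchor on one
        # side (sometimes both): short-anchor side(s) are false positives
        L = self._length()
        o = int(self.rng.integers(1, 3))
        gap = self._intron()
        span = o + gap + L  # spliced footprint
        # reserve 30 bp of left margin so a second, longer-intron spliced
        # alignment sharing the downstream block always fits
        ref, qpos = self._pick_ref(span + 31)
        qpos += 30
        # contiguous alignment covering the spliced alignment's long block
        p = qpos + gap + o - 1  # contiguous start; spliced 2nd block at p+1
        both_fp = self.rng.random() < 0.25
        if both_fp:
            # same downstream block, different intron length: overlapping,
            # non-identical, both with a short anchor
            gap2 = gap + int(self.rng.integers(3, 30))
            qpos2 = qpos - (gap2 - gap)
            a = [self._unique(q, ref, qpos2, f"{o}M{gap2}N{L - o}M")]
            b = [self._unique(q, ref, qpos, f"{o}M{gap}N{L - o}M")]
            la = lb = Label.FP
        else:
            a = [self._unique(q, ref, p, f"{L}M")]
            b = [self._unique(q, ref, qpos, f"{o}M{gap}N{L - o}M")]
            la, lb = Label.TP, Label.FP
            if self.rng.random() < 0.5:
                a, b = b, a
                la, lb = lb, la
        return a, b, la, lb

    def _s4(self, q: str):
        L = self._length()
        mode = self.rng.random()
        r1, p1 = self._pick_ref(L)
        if mode < 0.4 and len(self.spec.references) > 1:
            r2, p2 = self._pick_ref(L, exclude=r1)
            rev2 = False
        elif mode < 0.8:
            # same chromosome, disjoint coordinates
            r2, rev2 = r1, False
            ref_len = self.spec.references[r1]
            for _ in range(100):
                p2 = int(self.rng.integers(1, ref_len - L + 1))
                if abs(p2 - p1) >= 2 * L:
                    break
            else:
                # reference too small for disjoint placement
                p2, rev2 = p1, True
        else:
            # opposite strand at the same spot: different location by design
            r2, p2, rev2 = r1, p1, True
        a = [self._unique(q, r1, p1, f"{L}M")]
        b = [self._unique(q, r2, p2, f"{L}M", rev2)]
        return a, b, Label.FP, Label.FP

    def _s5(self, q: str):
        L = self._length()
        ref, pos = self._pick_ref(L)
        unique = [self._unique(q, ref, pos, f"{L}M")]
        multi = self._multi_group(q)
        if self.rng.random() < 0.5:
            return unique, multi, Label.FP, Label.TN
        return multi, unique, Label.TN, Label.FP

    def _s6(self, q: str):
        L = self._length()
        ref, pos = self._pick_ref(L)
        unique = [self._unique(q, ref, pos, f"{L}M")]
        missing = self._unmapped(q)
        if self.rng.random() < 0.5:
            return unique, missing, Label.TP, Label.NONE
        return missing, unique, Label.NONE, Label.TP

    def _s7(self, q: str):
        return self._multi_group(q), self._multi_group(q), Label.TN, Label.TN

    def _s8(self, q: str):
        multi = self._multi_group(q)
        missing = self._unmapped(q)
        if self.rng.random() < 0.5:
            return multi, missing, Label.TN, Label.NONE
        return missing, multi, Label.NONE, Label.TN


def generate(spec: ScenarioMixSpec) -> Tuple[str, str, TruthTable]:
    """Generate a name-sorted SAM file pair with known truth.

    Returns ``(sam_a, sam_b, truth)`` where the first two are complete
    SAM texts (header plus records) and the truth table lists every
    read's scenario and per-side labels. Deterministic given the spec's
    seed.
    """
    rng = np.random.default_rng(spec.seed)
    builder = _ReadBuilder(spec, rng)
    scenarios = sorted(spec.proportions)
    probs = np.array([spec.proportions[s] for s in scenarios], dtype=float)
    probs /= probs.sum()

    recs_a: List[_Rec] = []
    recs_b: List[_Rec] = []
    truth = TruthTable(seed=spec.seed)
    width = max(5, len(str(spec.n_reads)))
    for i in range(spec.n_reads):
        qname = f"r{i:0{width}d}"
        scenario = int(rng.choice(scenarios, p=probs))
        a, b, la, lb = builder.build(qname, scenario)
        recs_a.extend(a)
        recs_b.extend(b)
        truth.rows.append((qname, scenario, la, lb))

    sam_a = _sam_text(recs_a, spec.references, rng)
    sam_b = _sam_text(recs_b, spec.references, rng)
    return sam_a, sam_b, truth


# ---------------------------------------------------------------------------
# Built-in worked examples

_WX_REFERENCES: Dict[str, int] = {
    "1": 195_471_971,
    "2": 182_113_224,
    "7": 145_441_459,
    "11": 122_082_543,
    "MT": 16_299,
}


def builtin_worked_examples() -> Tuple[str, str, TruthTable]:
    """Three fixed reads exercising the short-anchor, discordant and
    unique-versus-multimapped discordance classes at real genomic
    coordinates.

    Side A plays the aligner that resolves all three reads correctly
    relative to its counterpart; side B uniquely maps all three.
    Expected tally: A TP=1 FP=1 TN=1; B FP=3.
    """
    rng = np.random.default_rng(7)
    truth = TruthTable()

    # 40-nt read: A contiguous on chromosome 2; B splices the same read
    # with a single base reaching across a 257-bp intron (1M 257N 39M).
    ex1_a = _Rec("ex1", 0, "2", 152_318_712, "40M", 40, nh=1)
    ex1_b = _Rec("ex1", 0, "2", 152_318_455, "1M257N39M", 40, nh=1)
    truth.rows.append(("ex1", 3, Label.TP, Label.FP))

    # 40-nt read uniquely placed on two different chromosomes: each
    # aligner missed the location the other found, so both are FP.
    ex2_a = _Rec("ex2", 0, "11", 109_011_648, "40M", 40, nh=1)
    ex2_b = _Rec("ex2", 0, "7", 110_059_825, "40M", 40, nh=1)
    truth.rows.append(("ex2", 4, Label.FP, Label.FP))

    # 51-nt read: A reports it twice (mitochondrial plus a spliced
    # nuclear alignment spanning 24,615,063-24,615,663), i.e. a
    # multimapping true negative; B reports the mitochondrial hit as
    # unique, a false positive. The nuclear CIGAR is synthesised to fill
    # the printed span; the labels do not depend on its exact split.
    ex3_a1 = _Rec("ex3", 0, "MT", 7_465, "51M", 51, nh=2)
    ex3_a2 = _Rec("ex3", 256, "1", 24_615_063, "25M550N26M", 0, nh=2)
    ex3_b = _Rec("ex3", 0, "MT", 7_465, "51M", 51, nh=1)
    truth.rows.append(("ex3", 5, Label.TN, Label.FP))

    sam_a = _sam_text([ex1_a, ex2_a, ex3_a1, ex3_a2], _WX_REFERENCES, rng)
    sam_b = _sam_text([ex1_b, ex2_b, ex3_b], _WX_REFERENCES, rng)
    return sam_a, sam_b, truth


def write_pair(sam_a: str, sam_b: str, directory,
               stem_a: str = "aligner_a", stem_b: str = "aligner_b"
               ) -> Tuple[Path, Path]:
    """Write the two SAM texts to ``directory`` and return the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path_a = directory / f"{stem_a}.sam"
    path_b = directory / f"{stem_b}.sam"
    path_a.write_text(sam_a)
    path_b.write_text(sam_b)
    return path_a, path_b
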