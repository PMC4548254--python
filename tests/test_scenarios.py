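"""Scenario-classification tests: pair predicates, decision table,
stream comparison, symmetry and oracle agreement."""

import pytest

from alncompare import (
    AlncompareError,
    Label,
    MappingStatus,
    ScenarioMixSpec,
    classify_pair,
    compare_streams,
    generate,
    group_from_records,
    overlapping,
    same_alignment,
    splice_label,
    stream_read_groups,
    write_pair,
)
from alncompare.sam_model import ReadMappingGroup

from conftest import mk_rec, oracle_compare


class TestPairPredicates:
    def test_identical_alignments_are_same(self):
        a = mk_rec(ref="chr2", start=152_318_712, cigar="40M")
        b = mk_rec(ref="chr2", start=152_318_712, cigar="40M")
        assert same_alignment(a, b)

    def test_different_block_structure_is_not_same_but_overlaps(self):
        a = mk_rec(ref="chr2", start=152_318_455, cigar="1M257N39M")
        b = mk_rec(ref="chr2", start=152_318_712, cigar="40M")
        assert not same_alignment(a, b)
        assert overlapping(a, b)

    def test_different_chromosomes_do_not_overlap(self):
        a = mk_rec(ref="chr11", start=109_011_648, cigar="40M")
        b = mk_rec(ref="chr7", start=110_059_825, cigar="40M")
        assert not same_alignment(a, b) and not overlapping(a, b)

    def test_opposite_strand_is_neither_same_nor_overlapping(self):
        a = mk_rec(start=100, cigar="40M", strand="+")
        b = mk_rec(start=100, cigar="40M", strand="-")
        assert not same_alignment(a, b) and not overlapping(a, b)

    def test_adjacent_blocks_do_not_overlap(self):
        a = mk_rec(start=100, cigar="20M")
        b = mk_rec(start=120, cigar="20M")
        assert not overlapping(a, b)

    def test_shared_intron_only_is_not_overlap(self):
        # b lies entirely inside a's intron gap
        a = mk_rec(start=100, cigar="10M500N10M")
        b = mk_rec(start=200, cigar="40M")
        assert not overlapping(a, b)

    def test_soft_clips_do_not_affect_identity(self):
        a = mk_rec(start=100, cigar="40M")
        b = mk_rec(start=100, cigar="5S40M")
        assert same_alignment(a, b)


class TestSpliceLabel:
    @pytest.mark.parametrize(
        "cigar, expected",
        [
            ("40M", Label.TP),          # un-spliced
            ("1M257N39M", Label.FP),    # 1-base anchor
            ("2M100N38M", Label.FP),    # 2-base anchor
            ("3M100N37M", Label.TP),    # shortest anchor 3: sound
            ("20M100N20M", Label.TP),
        ],
    )
    def test_default_threshold(self, cigar, expected):
        assert splice_label(mk_rec(cigar=cigar)) is expected

    def test_threshold_is_configurable(self):
        rec = mk_rec(cigar="4M100N36M")
        assert splice_label(rec) is Label.TP
        assert splice_label(rec, overhang_threshold=5) is Label.FP


def _ugroup(key="r1", **kw):
    return group_from_records(key, [mk_rec(key=key, nh=1, **kw)])


def _mgroup(key="r1"):
    return group_from_records(key, [
        mk_rec(key=key, start=100, nh=2),
        mk_rec(key=key, ref="chr2", start=5_000, nh=2, secondary=True),
    ])


def _xgroup(key="r1", absent=False):
    records = [] if absent else [mk_rec(key=key, mapped=False)]
    return group_from_records(key, records)


class TestClassifyPair:
    def test_same_unique_alignment_is_concordant(self):
        call = classify_pair(_ugroup(start=100), _ugroup(start=100))
        assert (call.scenario, call.label_a, call.label_b) == (
            1, Label.TP, Label.TP)

    def test_overlapping_sound_alignments(self):
        call = classify_pair(
            _ugroup(start=100, cigar="40M"),
            _ugroup(start=100, cigar="20M300N20M"),
        )
        assert (call.scenario, call.label_a, call.label_b) == (
            2, Label.TP, Label.TP)

    def test_short_anchor_splice_side_is_false_positive(self):
        call = classify_pair(
            _ugroup(start=152_318_712, cigar="40M", ref="chr2"),
            _ugroup(start=152_318_455, cigar="1M257N39M", ref="chr2"),
        )
        assert (call.scenario, call.label_a, call.label_b) == (
            3, Label.TP, Label.FP)

    def test_both_sides_short_anchor_both_false_positive(self):
        call = classify_pair(
            _ugroup(start=90, cigar="2M110N38M"),
            _ugroup(start=100, cigar="2M100N38M"),
        )
        assert (call.scenario, call.label_a, call.label_b) == (
            3, Label.FP, Label.FP)

    def test_discordant_unique_locations(self):
        call = classify_pair(
            _ugroup(start=109_011_648, ref="chr1"),
            _ugroup(start=110_059_825, ref="chr2"),
        )
        assert (call.scenario, call.label_a, call.label_b) == (
            4, Label.FP, Label.FP)

    @pytest.mark.parametrize("swap", [False, True])
    def test_unique_versus_multimapped(self, swap):
        u, m = _ugroup(), _mgroup()
        call = classify_pair(m, u) if swap else classify_pair(u, m)
        assert call.scenario == 5
        if swap:
            assert (call.label_a, call.label_b) == (Label.TN, Label.FP)
        else:
            assert (call.label_a, call.label_b) == (Label.FP, Label.TN)

    @pytest.mark.parametrize("absent", [False, True])
    def test_unique_versus_unmapped(self, absent):
        call = classify_pair(_ugroup(), _xgroup(absent=absent))
        assert (call.scenario, call.label_a, call.label_b) == (
            6, Label.TP, Label.NONE)

    def test_both_multimapped(self):
        call = classify_pair(_mgroup(), _mgroup())
        assert (call.scenario, call.label_a, call.label_b) == (
            7, Label.TN, Label.TN)

    @pytest.mark.parametrize("absent", [False, True])
    def test_multimapped_versus_unmapped(self, absent):
        call = classify_pair(_xgroup(absent=absent), _mgroup())
        assert (call.scenario, call.label_a, call.label_b) == (
            8, Label.NONE, Label.TN)

    def test_both_unmapped_rejected(self):
        with pytest.raises(AlncompareError):
            classify_pair(_xgroup(), _xgroup(absent=True))

    def test_mismatched_keys_rejected(self):
        with pytest.raises(AlncompareError):
            classify_pair(_ugroup("r1"), _ugroup("r2"))


class TestCompareStreams:
    def _run(self, tmp_path, seed=0, n_reads=50, proportions=None):
        spec = ScenarioMixSpec(
            n_reads=n_reads,
            proportions=proportions or {s: 0.125 for s in range(1, 9)},
            seed=seed,
        )
        sam_a, sam_b, truth = generate(spec)
        pa, pb = write_pair(sam_a, sam_b, tmp_path / f"s{seed}")
        calls, tally = compare_streams(
            stream_read_groups(pa), stream_read_groups(pb)
        )
        return pa, pb, truth, calls, tally

    def test_every_read_gets_exactly_one_scenario(self, tmp_path):
        _, _, truth, calls, tally = self._run(tmp_path, seed=3)
        assert len(calls) == len({c.read_key for c in calls}) == len(truth.rows)
        assert sum(tally.scenario_counts.values()) == len(calls)

    def test_self_comparison_has_no_false_positives(self, tmp_path):
        pa, _, _, _, _ = self._run(tmp_path, seed=1)
        calls, tally = compare_streams(
            stream_read_groups(pa), stream_read_groups(pa)
        )
        assert tally.fp_a == tally.fp_b == 0
        assert all(c.scenario in (1, 6, 7, 8) for c in calls)
        # 6/8 never occur in self-comparison: both sides map identically
        assert all(c.scenario in (1, 7) for c in calls)

    def test_swapping_inputs_swaps_sides(self, tmp_path):
        pa, pb, _, calls_ab, tally_ab = self._run(tmp_path, seed=5)
        calls_ba, tally_ba = compare_streams(
            stream_read_groups(pb), stream_read_groups(pa)
        )
        assert (tally_ab.tp_a, tally_ab.fp_a, tally_ab.tn_a) == (
            tally_ba.tp_b, tally_ba.fp_b, tally_ba.tn_b)
        assert (tally_ab.tp_b, tally_ab.fp_b, tally_ab.tn_b) == (
            tally_ba.tp_a, tally_ba.fp_a, tally_ba.tn_a)
        by_key = {c.read_key: c for c in calls_ba}
        for call in calls_ab:
            swapped = by_key[call.read_key]
            assert (swapped.label_a, swapped.label_b) == (
                call.label_b, call.label_a)
            assert swapped.scenario == call.scenario

    def test_streaming_agrees_with_brute_force_oracle(self, tmp_path):
        for seed in range(5):
            pa, pb, _, calls, _ = self._run(tmp_path, seed=seed)
            expected = oracle_compare(pa, pb)
            got = {
                c.read_key: (c.scenario, c.label_a.value, c.label_b.value)
                for c in calls
            }
            assert got == expected

    def test_order_independence(self, tmp_path):
        # side B re-ordered: keyed join must produce identical calls
        pa, pb, _, calls, _ = self._run(tmp_path, seed=7)
        lines = pb.read_text().splitlines()
        header = [l for l in lines if l.startswith("@")]
        body = [l for l in lines if not l.startswith("@")]
        # reverse read blocks while keeping records of a read adjacent
        from itertools import groupby
        blocks = [list(g) for _, g in groupby(body, key=lambda l: l.split("\t")[0])]
        shuffled = tmp_path / "b_shuffled.sam"
        shuffled.write_text(
            "\n".join(header + [l for blk in reversed(blocks) for l in blk]) + "\n"
        )
        calls2, _ = compare_streams(
            stream_read_groups(pa), stream_read_groups(shuffled)
        )
        assert {
            (c.read_key, c.scenario, c.label_a, c.label_b) for c in calls
        } == {(c.read_key, c.scenario, c.label_a, c.label_b) for c in calls2}
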