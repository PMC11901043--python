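import random

import pytest

from conftest import make_frame
from oracles import brute_force_max_tp

from frameie.datamodel import Relation
from frameie.evaluation import (
    EvalCounts,
    MatchMode,
    UnknownLabelKeyError,
    evaluate_attributes,
    evaluate_relations,
    frame_matching,
    match_frames,
    matching_by_id,
)


def random_frames(rng, n_max=6, with_labels=True):
    frames = []
    for i in range(rng.randint(0, n_max)):
        start = rng.randint(0, 12)
        attrs = {"Type": rng.choice(["Drug", "Condition"])} if with_labels else {}
        frames.append(make_frame(i, start, start + rng.randint(1, 5), **attrs))
    return frames


class TestMatchFrames:
    def test_identical_frame_is_strict_tp(self):
        gold = [make_frame(0, 0, 7, Type="Drug")]
        pred = [make_frame(0, 0, 7, Type="Drug")]
        counts = match_frames(gold, pred, "strict", label_key="Type")
        assert (counts.tp, counts.fp, counts.fn) == (1, 0, 0)

    def test_off_by_one_span_fails_strict_passes_relaxed(self):
        gold = [make_frame(0, 0, 7, Type="Drug")]
        pred = [make_frame(0, 0, 6, Type="Drug")]
        strict = match_frames(gold, pred, "strict", label_key="Type")
        relaxed = match_frames(gold, pred, "relaxed", label_key="Type")
        assert (strict.tp, strict.fp, strict.fn) == (0, 1, 1)
        assert (relaxed.tp, relaxed.fp, relaxed.fn) == (1, 0, 0)

    def test_label_mismatch_blocks_both_modes(self):
        gold = [make_frame(0, 0, 7, Type="Drug")]
        pred = [make_frame(0, 0, 7, Type="Condition")]
        for mode in MatchMode:
            assert match_frames(gold, pred, mode, label_key="Type").tp == 0

    def test_without_label_key_spans_alone_decide(self):
        gold = [make_frame(0, 0, 7, Type="Drug")]
        pred = [make_frame(0, 0, 7, Type="Condition")]
        assert match_frames(gold, pred, "strict").tp == 1

    def test_unknown_label_key_raises(self):
        gold = [make_frame(0, 0, 7, Type="Drug")]
        pred = [make_frame(0, 0, 7, Type="Drug")]
        with pytest.raises(UnknownLabelKeyError):
            match_frames(gold, pred, "strict", label_key="Colour")

    def test_matching_is_maximum_not_greedy(self):
        # greedy left-to-right pairing of gold[0] with pred[0] blocks pred[1];
        # the maximum matching pairs gold[0]-pred[1] and gold[1]-pred[0]
        gold = [make_frame(0, 0, 10), make_frame(1, 0, 4)]
        pred = [make_frame(0, 0, 4), make_frame(1, 5, 10)]
        assert match_frames(gold, pred, "relaxed").tp == 2

    def test_equals_brute_force_over_all_assignments(self):
        rng = random.Random(20260921)
        for _ in range(300):
            gold = random_frames(rng)
            pred = random_frames(rng)
            if not any("Type" in f.attributes for f in gold + pred):
                continue
            strict = match_frames(gold, pred, "strict", label_key="Type")
            relaxed = match_frames(gold, pred, "relaxed", label_key="Type")
            assert strict.tp == brute_force_max_tp(gold, pred, "strict", "Type")
            assert relaxed.tp == brute_force_max_tp(gold, pred, "relaxed", "Type")
            assert strict.tp <= relaxed.tp
            assert strict.tp + strict.fp == len(pred)
            assert strict.tp + strict.fn == len(gold)


class TestEvalCounts:
    @pytest.mark.parametrize(
        "tp,fp,fn,p,r",
        [(0, 0, 0, 0.0, 0.0), (1, 0, 0, 1.0, 1.0), (1, 1, 3, 0.5, 0.25)],
    )
    def test_metric_definitions_and_zero_denominators(self, tp, fp, fn, p, r):
        c = EvalCounts(tp, fp, fn)
        assert c.precision == p and c.recall == r
        assert 0.0 <= c.f1 <= 1.0
        if tp == 0:
            assert c.f1 == 0.0

    def test_metrics_bounded_on_random_counts(self):
        rng = random.Random(3)
        for _ in range(100):
            c = EvalCounts(rng.randint(0, 20), rng.randint(0, 20), rng.randint(0, 20))
            assert 0.0 <= c.precision <= 1.0
            assert 0.0 <= c.recall <= 1.0
            assert 0.0 <= c.f1 <= 1.0


class TestEvaluateAttributes:
    def gold_pred(self):
        gold = [
            make_frame(0, 0, 7, Type="Drug", Dosage="81 mg"),
            make_frame(1, 10, 14, Type="Drug", Dosage="5 mg"),
            make_frame(2, 20, 24, Type="Drug", Dosage="10 mg"),
        ]
        pred = [
            make_frame(0, 0, 7, Type="Drug", Dosage="81 mg"),
            make_frame(1, 10, 14, Type="Drug", Dosage="5mg"),
        ]
        return gold, pred

    def test_equal_trimmed_value_is_tp(self):
        gold, pred = self.gold_pred()
        counts = evaluate_attributes(gold, pred, "strict", ["Dosage"], label_key="Type")
        assert counts["Dosage"].tp == 1

    def test_inner_whitespace_difference_is_error_both_ways(self):
        gold, pred = self.gold_pred()
        counts = evaluate_attributes(gold, pred, "strict", ["Dosage"], label_key="Type")
        # "5 mg" vs "5mg" wrong on a matched pair; unmatched gold frame adds fn
        assert counts["Dosage"].fp == 1
        assert counts["Dosage"].fn == 2

    def test_surrounding_whitespace_is_trimmed(self):
        gold = [make_frame(0, 0, 7, Dosage="81 mg")]
        pred = [make_frame(0, 0, 7, Dosage=" 81 mg ")]
        counts = evaluate_attributes(gold, pred, "strict", ["Dosage"])
        assert counts["Dosage"].tp == 1

    def test_key_absent_from_both_sides_of_a_pair_not_counted(self):
        gold = [make_frame(0, 0, 7)]
        pred = [make_frame(0, 0, 7)]
        counts = evaluate_attributes(gold, pred, "strict", ["Dosage"])
        assert (counts["Dosage"].tp, counts["Dosage"].fp, counts["Dosage"].fn) == (0, 0, 0)


class TestEvaluateRelations:
    def test_identical_relation_over_matched_frames(self):
        gold = [Relation("g0", "g1", "ADE-Drug")]
        pred = [Relation("p0", "p1", "ADE-Drug")]
        counts = evaluate_relations(gold, pred, {"p0": "g0", "p1": "g1"})
        assert (counts.tp, counts.fp, counts.fn) == (1, 0, 0)

    def test_order_insensitive_pairing(self):
        gold = [Relation("g0", "g1", "ADE-Drug")]
        pred = [Relation("p1", "p0", "ADE-Drug")]
        assert evaluate_relations(gold, pred, {"p0": "g0", "p1": "g1"}).tp == 1

    def test_unmatched_frames_make_fp(self):
        gold = [Relation("g0", "g1", "ADE-Drug")]
        pred = [Relation("p0", "p1", "ADE-Drug")]
        counts = evaluate_relations(gold, pred, {})
        assert (counts.tp, counts.fp, counts.fn) == (0, 1, 1)

    def test_type_mismatch_is_not_tp(self):
        gold = [Relation("g0", "g1", "ADE-Drug")]
        pred = [Relation("p0", "p1", "Condition-Drug")]
        counts = evaluate_relations(gold, pred, {"p0": "g0", "p1": "g1"})
        assert counts.tp == 0

    def test_partial_recovery_recall(self):
        gold = [Relation("g0", "g1", "ADE-Drug"), Relation("g0", "g2", "Condition-Drug")]
        pred = [Relation("p0", "p1", "ADE-Drug")]
        counts = evaluate_relations(gold, pred, {"p0": "g0", "p1": "g1"})
        assert counts.recall == 0.5

    def test_gold_relation_consumed_at_most_once(self):
        gold = [Relation("g0", "g1", "ADE-Drug")]
        pred = [Relation("p0", "p1", "ADE-Drug"), Relation("p1", "p0", "ADE-Drug")]
        counts = evaluate_relations(gold, pred, {"p0": "g0", "p1": "g1"})
        assert (counts.tp, counts.fp) == (1, 1)


class TestMatchingHelpers:
    def test_matching_by_id_maps_pred_to_gold(self):
        gold = [make_frame("g", 0, 7)]
        pred = [make_frame("p", 0, 7)]
        assert matching_by_id(gold, pred) == {"p": "g"}

    def test_empty_sides_give_empty_matching(self):
        assert frame_matching([], [make_frame(0, 0, 1)]) == []
        assert frame_matching([make_frame(0, 0, 1)], []) == []
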