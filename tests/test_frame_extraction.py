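import json
import random

import pytest

from oracles import brute_force_ground, random_grounding_instance

from frameie.engine import ScriptedEngine, ScriptExhaustedError
from frameie.frame_extraction import (
    RawEntityItem,
    build_frame_prompt,
    extract_basic,
    extract_review,
    extract_sentence,
    ground_spans,
    parse_frames_json,
    split_sentences,
)

TEMPLATE = "Extract entities.\n{{input}}"


def items(*texts):
    return [RawEntityItem(entity_text=t, attributes={}) for t in texts]


class TestSplitSentences:
    def test_terminator_plus_space_splits(self):
        spans = split_sentences("Pt on aspirin. Rash noted.")
        assert [(s.start, s.end) for s in spans] == [(0, 14), (15, 26)]
        assert spans[0].text == "Pt on aspirin."

    def test_empty_text(self):
        assert split_sentences("") == []

    def test_no_terminator_whole_text(self):
        spans = split_sentences("no terminator")
        assert [(s.start, s.end) for s in spans] == [(0, 13)]

    def test_newline_is_hard_break(self):
        spans = split_sentences("line one\nline two")
        assert [s.text for s in spans] == ["line one", "line two"]

    @pytest.mark.parametrize(
        "text",
        [
            "Dr. note? Yes! Stop.",
            "a\n\nb",
            "  leading space. and trailing  ",
            "Multiple!!! terminators?! here. end",
        ],
    )
    def test_spans_slice_document_and_are_ordered(self, text):
        spans = split_sentences(text)
        prev_end = -1
        for s in spans:
            assert text[s.start : s.end] == s.text
            assert s.start > prev_end or prev_end == -1
            assert s.start >= prev_end
            prev_end = s.end


class TestParseFramesJson:
    def test_code_fence_tolerated(self):
        raw = '```json\n[{"entity_text":"aspirin","Type":"Drug"}]\n```'
        out = parse_frames_json(raw)
        assert out == [RawEntityItem("aspirin", {"Type": "Drug"})]

    def test_elements_without_entity_text_discarded(self):
        out = parse_frames_json('[{"entity_text":"aspirin"},{"Type":"Drug"}]')
        assert [i.entity_text for i in out] == ["aspirin"]

    def test_surrounding_prose_tolerated(self):
        raw = 'Sure! Here are the entities: [{"entity_text":"rash"}] Hope this helps.'
        assert [i.entity_text for i in parse_frames_json(raw)] == ["rash"]

    @pytest.mark.parametrize(
        "raw", ["maybe?", "", "[unclosed", '{"entity_text":"x"}', "[1, 2"]
    )
    def test_unparseable_input_returns_empty_list(self, raw):
        assert parse_frames_json(raw) == []

    def test_non_object_and_empty_text_elements_discarded(self):
        raw = '[1, "x", {"entity_text": ""}, {"entity_text": "ok"}, null]'
        assert [i.entity_text for i in parse_frames_json(raw)] == ["ok"]

    def test_attribute_values_stringified(self):
        out = parse_frames_json('[{"entity_text":"a","n":81,"flag":true}]')
        assert out[0].attributes == {"n": "81", "flag": "true"}

    def test_earlier_invalid_bracket_skipped(self):
        raw = 'scores [1/2] then [{"entity_text":"rash"}]'
        assert [i.entity_text for i in parse_frames_json(raw)] == ["rash"]


class TestGroundSpans:
    def test_repeated_mention_maps_to_successive_occurrences(self):
        frames = ground_spans("aspirin 81 mg; aspirin held", 0, items("aspirin", "aspirin"))
        assert [(f.start, f.end) for f in frames] == [(0, 7), (15, 22)]

    def test_absent_item_dropped(self):
        assert ground_spans("aspirin 81 mg", 0, items("ibuprofen")) == []

    def test_case_insensitive_fallback_stores_document_slice(self):
        frames = ground_spans("aspirin 81 mg", 0, items("Aspirin"))
        assert [(f.start, f.end) for f in frames] == [(0, 7)]
        assert frames[0].entity_text == "aspirin"

    def test_whitespace_normalized_fallback(self):
        frames = ground_spans("took  81   mg today", 0, items("81 mg"))
        assert [(f.start, f.end) for f in frames] == [(6, 13)]
        assert frames[0].entity_text == "81   mg"

    def test_region_offset_shifts_spans(self):
        frames = ground_spans("has rash", 100, items("rash"))
        assert (frames[0].start, frames[0].end) == (104, 108)

    def test_matches_exhaustive_leftmost_unconsumed_oracle(self):
        rng = random.Random(42)
        for _ in range(200):
            region, entity_texts = random_grounding_instance(rng)
            frames = ground_spans(region, 0, items(*entity_texts))
            expected = brute_force_ground(region, entity_texts)
            assert [(f.start, f.end) for f in frames] == expected
            for f in frames:
                assert region[f.start : f.end] == f.entity_text


class TestExtractBasic:
    def test_single_call_yields_grounded_frames(self):
        text = "aspirin 81 mg"
        prompt = build_frame_prompt(TEMPLATE, text)
        engine = ScriptedEngine(exact={prompt: '[{"entity_text":"aspirin","Type":"Drug"}]'})
        frames = extract_basic(text, TEMPLATE, engine)
        assert engine.call_count == 1
        assert [(f.frame_id, f.start, f.end) for f in frames] == [("0", 0, 7)]
        assert frames[0].attributes == {"Type": "Drug"}

    def test_empty_array_yields_no_frames(self):
        engine = ScriptedEngine(queue=["[]"])
        assert extract_basic("text here", TEMPLATE, engine) == []

    def test_hallucinated_entity_dropped(self):
        engine = ScriptedEngine(queue=['[{"entity_text":"warfarin"}]'])
        assert extract_basic("aspirin only", TEMPLATE, engine) == []


class TestExtractReview:
    def test_addition_unions_initial_and_review(self):
        text = "aspirin caused rash"
        engine = ScriptedEngine(
            queue=['[{"entity_text":"aspirin"}]', '[{"entity_text":"rash"}]']
        )
        frames = extract_review(text, TEMPLATE, engine, mode="addition")
        assert engine.call_count == 2
        assert [(f.start, f.end) for f in frames] == [(0, 7), (15, 19)]
        assert [f.frame_id for f in frames] == ["0", "1"]

    def test_addition_deduplicates_repeats(self):
        text = "aspirin caused rash"
        engine = ScriptedEngine(
            queue=['[{"entity_text":"aspirin"}]', '[{"entity_text":"aspirin"}]']
        )
        frames = extract_review(text, TEMPLATE, engine, mode="addition")
        assert len(frames) == 1

    def test_revision_replaces_initial(self):
        engine = ScriptedEngine(queue=['[{"entity_text":"aspirin"}]', "[]"])
        assert extract_review("aspirin", TEMPLATE, engine, mode="revision") == []

    def test_review_turn_carries_initial_completion(self):
        engine = ScriptedEngine(queue=['[{"entity_text":"aspirin"}]', "[]"])
        extract_review("aspirin", TEMPLATE, engine)
        second_call_messages = engine.call_log[1][0]
        roles = [m.role for m in second_call_messages]
        assert roles == ["user", "assistant", "user"]
        assert second_call_messages[1].content == '[{"entity_text":"aspirin"}]'

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            extract_review("x", TEMPLATE, ScriptedEngine(), mode="bogus")


class TestExtractSentence:
    TEXT = "Pt on aspirin. Aspirin held."

    def script_for(self, completions):
        sents = split_sentences(self.TEXT)
        return ScriptedEngine(
            exact={
                build_frame_prompt(TEMPLATE, s.text): c
                for s, c in zip(sents, completions)
            }
        )

    def test_one_call_per_sentence_frames_in_own_sentence(self):
        engine = self.script_for(
            ['[{"entity_text":"aspirin"}]', '[{"entity_text":"Aspirin"}]']
        )
        frames = extract_sentence(self.TEXT, TEMPLATE, engine)
        assert engine.call_count == 2
        assert [(f.frame_id, f.start, f.end) for f in frames] == [("0", 6, 13), ("1", 15, 22)]
        # each grounded in its own sentence, never cross-matched
        assert frames[0].entity_text == "aspirin"
        assert frames[1].entity_text == "Aspirin"

    def test_garbage_sentence_does_not_abort_run(self):
        engine = self.script_for(["complete garbage", '[{"entity_text":"Aspirin"}]'])
        frames = extract_sentence(self.TEXT, TEMPLATE, engine)
        assert [(f.start, f.end) for f in frames] == [(15, 22)]

    def test_engine_failure_skipped_unless_fail_fast(self):
        sents = split_sentences(self.TEXT)
        only_second = ScriptedEngine(
            exact={build_frame_prompt(TEMPLATE, sents[1].text): '[{"entity_text":"Aspirin"}]'}
        )
        frames = extract_sentence(self.TEXT, TEMPLATE, only_second)
        assert [(f.start, f.end) for f in frames] == [(15, 22)]
        with pytest.raises(ScriptExhaustedError):
            extract_sentence(self.TEXT, TEMPLATE, ScriptedEngine(), fail_fast=True)


class TestPromptAssembly:
    def test_few_shot_examples_precede_input(self):
        few_shot = [{"input": "ex in", "output": "ex out"}]
        prompt = build_frame_prompt(TEMPLATE, "the note", few_shot)
        assert "Input: ex in\nOutput: ex out" in prompt
        assert prompt.index("ex in") < prompt.index("the note")
        assert prompt.rstrip().endswith("Output:")

    def test_template_without_placeholder_rejected(self):
        with pytest.raises(ValueError):
            build_frame_prompt("no slot", "text")
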