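"""Frame extraction: prompting algorithms and post-processing.

Three prompting algorithms turn a document plus a prompt template into
grounded frames:

* :func:`extract_basic` — one chat call on the whole document.  Efficient
  for sparse tasks with few entities.
* :func:`extract_review` — a second "amend and correct" turn after the
  initial call; ``addition`` mode unions the two passes (higher recall),
  ``revision`` mode keeps only the reviewed output.
* :func:`extract_sentence` — one call per sentence; grounding each
  completion within its own sentence improves recall and span accuracy on
  dense documents.

Post-processing is deliberately forgiving: the model's completion is scanned
for the first balanced JSON array (prose and code fences around it are
tolerated), elements without a usable ``entity_text`` are discarded, and
entity texts that cannot be located in the source region are dropped with a
warning.  Every frame that survives satisfies
``document_text[start:end] == entity_text``.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass

from .datamodel import Frame
from .engine import GenerationConfig, InferenceEngine, assistant, user
from .templating import list_placeholders, render

logger = logging.getLogger(__name__)

__all__ = [
    "SentenceSpan",
    "RawEntityItem",
    "split_sentences",
    "parse_frames_json",
    "ground_spans",
    "build_frame_prompt",
    "extract_basic",
    "extract_review",
    "extract_sentence",
    "REVIEW_INSTRUCTION_ADDITION",
    "REVIEW_INSTRUCTION_REVISION",
]

ENTITY_TEXT_KEY = "entity_text"

REVIEW_INSTRUCTION_ADDITION = (
    "Review your output above against the original text. List any entities "
    "you missed, using the same JSON format. Output only the additional "
    "entities as a JSON array; output [] if nothing was missed."
)
REVIEW_INSTRUCTION_REVISION = (
    "Review your output above against the original text for missed entities "
    "and mistakes. Output the complete corrected list of entities as a JSON "
    "array in the same format."
)


@dataclass(frozen=True)
class SentenceSpan:
    """A sentence with document-level character offsets (half-open)."""

    text: str
    start: int
    end: int


@dataclass(frozen=True)
class RawEntityItem:
    """A parsed element of the model's JSON array, before grounding."""

    entity_text: str
    attributes: dict


# sentence boundary: terminator run followed by whitespace, or a hard newline
_BOUNDARY = re.compile(r"[.!?]+(?=\s)|\n")


def split_sentences(text: str) -> list[SentenceSpan]:
    """Rule-based, offset-preserving sentence splitter.

    Splits after a run of ``.``/``!``/``?`` followed by whitespace and at
    newlines; leading/trailing whitespace is excluded from each span.  Spans
    are non-overlapping, ordered, and slice the document exactly.
    """
    spans: list[SentenceSpan] = []
    cursor = 0
    for m in _BOUNDARY.finditer(text):
        boundary = m.end() if m.group() != "\n" else m.start()
        _append_trimmed(spans, text, cursor, boundary)
        cursor = m.end()
    _append_trimmed(spans, text, cursor, len(text))
    return spans


def _append_trimmed(spans: list[SentenceSpan], text: str, start: int, end: int) -> None:
    chunk = text[start:end]
    lead = len(chunk) - len(chunk.lstrip())
    trail = len(chunk) - len(chunk.rstrip())
    start, end = start + lead, end - trail
    if start < end:
        spans.append(SentenceSpan(text=text[start:end], start=start, end=end))


def parse_frames_json(raw: str) -> list[RawEntityItem]:
    """Extract entity items from a raw completion.

    Locates the first top-level balanced JSON array in ``raw`` (surrounding
    prose and markdown code fences are tolerated) and keeps, in order, the
    object elements carrying a non-empty string ``entity_text``.  All other
    keys of a kept element become attributes, values stringified.
    Inconsistent elements are discarded; wholly unparseable input yields an
    empty list with a warning, never an exception.
    """
    arr = _first_json_array(raw)
    if arr is None:
        logger.warning("no parseable JSON array in completion: %.120r", raw)
        return []
    items: list[RawEntityItem] = []
    for element in arr:
        if not isinstance(element, dict):
            logger.warning("discarding non-object element: %r", element)
            continue
        text = element.get(ENTITY_TEXT_KEY)
        if not isinstance(text, str) or not text:
            logger.warning("discarding element without entity_text: %r", element)
            continue
        attrs = {
            str(k): v if isinstance(v, str) else json.dumps(v)
            for k, v in element.items()
            if k != ENTITY_TEXT_KEY
        }
        items.append(RawEntityItem(entity_text=text, attributes=attrs))
    return items


def _first_json_array(raw: str) -> list | None:
    decoder = json.JSONDecoder()
    for idx, ch in enumerate(raw):
        if ch != "[":
            continue
        try:
            value, _ = decoder.raw_decode(raw, idx)
        except json.JSONDecodeError:
            continue
        if isinstance(value, list):
            return value
    return None


def _normalized_pattern(needle: str) -> re.Pattern:
    tokens = needle.split()
    return re.compile(r"\s+".join(re.escape(t) for t in tokens), re.IGNORECASE)


def ground_spans(region_text: str, region_offset: int, items: list[RawEntityItem]) -> list[Frame]:
    """Map entity texts back to character spans in the source region.

    Each item is matched to the leftmost occurrence of its ``entity_text``
    in ``region_text`` not already consumed by an earlier item of this call,
    so repeated mentions map to successive occurrences.  Matching is tried
    exact, then case-insensitive, then whitespace-normalized; the stored
    ``entity_text`` is always the document slice, so the grounding invariant
    holds regardless of tier.  Unmatched items are dropped with a warning.
    Returned frames carry document-level offsets and empty ``frame_id``
    (the caller assigns IDs).
    """
    consumed: list[tuple[int, int]] = []
    frames: list[Frame] = []
    for item in items:
        span = _find_unconsumed(region_text, item.entity_text, consumed)
        if span is None:
            logger.warning("cannot ground %r in region; item dropped", item.entity_text)
            continue
        start, end = span
        consumed.append(span)
        frames.append(
            Frame(
                frame_id="",
                start=region_offset + start,
                end=region_offset + end,
                entity_text=region_text[start:end],
                attributes=dict(item.attributes),
            )
        )
    return frames


def _find_unconsumed(region: str, needle: str, consumed: list[tuple[int, int]]) -> tuple[int, int] | None:
    def free(start: int, end: int) -> bool:
        return all(max(start, s) >= min(end, e) for s, e in consumed)

    # tier 1: exact
    pos = region.find(needle)
    while pos != -1:
        if free(pos, pos + len(needle)):
            return pos, pos + len(needle)
        pos = region.find(needle, pos + 1)
    # tier 2: case-insensitive
    low_region, low_needle = region.lower(), needle.lower()
    pos = low_region.find(low_needle)
    while pos != -1:
        if free(pos, pos + len(low_needle)):
            return pos, pos + len(low_needle)
        pos = low_region.find(low_needle, pos + 1)
    # tier 3: whitespace-normalized (also case-insensitive); scan every start
    # position so candidates overlapping a rejected one are still considered
    if needle.split():
        pattern = _normalized_pattern(needle)
        for start in range(len(region)):
            m = pattern.match(region, start)
            if m and m.end() > m.start() and free(m.start(), m.end()):
                return m.start(), m.end()
    return None


def build_frame_prompt(template: str, input_text: str, few_shot: list[dict] | None = None) -> str:
    """Render the extraction prompt for one input region.

    With few-shot examples, the input slot receives "Input/Output" blocks for
    each example followed by the actual input, so examples sit directly
    before the text to process while the template's schema and format
    instructions stay on top.
    """
    names = list_placeholders(template)
    if not names:
        raise ValueError("frame-extraction template must contain an input placeholder")
    slot = "input" if "input" in names else names[0]
    if few_shot:
        block = "".join(
            f"Input: {ex['input']}\nOutput: {ex['output']}\n\n" for ex in few_shot
        )
        value = f"{block}Input: {input_text}\nOutput:"
    else:
        value = input_text
    context = {name: "" for name in names}
    context[slot] = value
    return render(template, context)


def _assign_ids(frames: list[Frame]) -> list[Frame]:
    for i, frame in enumerate(frames):
        frame.frame_id = str(i)
    return frames


def extract_basic(
    text: str,
    template: str,
    engine: InferenceEngine,
    few_shot: list[dict] | None = None,
    config: GenerationConfig | None = None,
) -> list[Frame]:
    """Single-call extraction over the whole document."""
    prompt = build_frame_prompt(template, text, few_shot)
    completion = engine.chat([user(prompt)], config)
    return _assign_ids(ground_spans(text, 0, parse_frames_json(completion)))


def extract_review(
    text: str,
    template: str,
    engine: InferenceEngine,
    few_shot: list[dict] | None = None,
    config: GenerationConfig | None = None,
    mode: str = "addition",
) -> list[Frame]:
    """Two-turn extraction: initial pass, then a review turn.

    ``addition`` unions initial and review frames (deduplicated on span and
    text); ``revision`` replaces the initial output with the reviewed one.
    """
    if mode not in ("addition", "revision"):
        raise ValueError(f"mode must be 'addition' or 'revision', got {mode!r}")
    prompt = build_frame_prompt(template, text, few_shot)
    first = engine.chat([user(prompt)], config)
    instruction = (
        REVIEW_INSTRUCTION_ADDITION if mode == "addition" else REVIEW_INSTRUCTION_REVISION
    )
    second = engine.chat([user(prompt), assistant(first), user(instruction)], config)
    review_items = parse_frames_json(second)
    if mode == "revision":
        return _assign_ids(ground_spans(text, 0, review_items))
    initial = ground_spans(text, 0, parse_frames_json(first))
    merged = list(initial)
    seen = {(f.start, f.end, f.entity_text) for f in initial}
    for frame in ground_spans(text, 0, review_items):
        key = (frame.start, frame.end, frame.entity_text)
        if key not in seen:
            seen.add(key)
            merged.append(frame)
    return _assign_ids(merged)


def extract_sentence(
    text: str,
    template: str,
    engine: InferenceEngine,
    few_shot: list[dict] | None = None,
    config: GenerationConfig | None = None,
    fail_fast: bool = False,
) -> list[Frame]:
    """Sentence-by-sentence extraction.

    One chat call per sentence, in order; each completion is grounded within
    its own sentence so identical mentions in different sentences are never
    cross-matched.  A failed sentence is logged and skipped unless
    ``fail_fast`` is set.
    """
    frames: list[Frame] = []
    for sent in split_sentences(text):
        prompt = build_frame_prompt(template, sent.text, few_shot)
        try:
            completion = engine.chat([user(prompt)], config)
        except Exception:
            if fail_fast:
                raise
            logger.warning("engine failed on sentence (%d,%d); skipped", sent.start, sent.end)
            continue
        frames.extend(ground_spans(sent.text, sent.start, parse_frames_json(completion)))
    return _assign_ids(frames)
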