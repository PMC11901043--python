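"""Relation extraction over frame pairs.

Relations are decided one unordered frame pair at a time: the pair plus a
region of interest around it is substituted into a prompt template and the
model answers either whether a relation exists (:func:`extract_binary`) or
which type it has (:func:`extract_multiclass`).

The cost saver is the *possible-relation-types hook*: a caller-supplied pure
function that, from the two frames alone (typically their ``Type``
attributes), returns the admissible relation types for the pair.  Pairs
whose admissible set is empty — or contains only ``"No-relation"`` — are
skipped without any model call, e.g. two dosage mentions can never be
related, so no inference is spent on them.  Rule sets can be declared as
data (:func:`make_rule_hook`) or plugged in as arbitrary callables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Callable, Sequence

from .datamodel import Frame, IEDocument, Relation
from .engine import GenerationConfig, InferenceEngine, user
from .templating import list_placeholders, render

logger = logging.getLogger(__name__)

__all__ = [
    "NO_RELATION",
    "FramePair",
    "enumerate_pairs",
    "build_pair_context",
    "extract_binary",
    "extract_multiclass",
    "make_rule_hook",
    "make_binary_hook",
    "load_rules",
]

NO_RELATION = "No-relation"
DEFAULT_WINDOW = 200

BinaryHook = Callable[[Frame, Frame], bool]
MulticlassHook = Callable[[Frame, Frame], Sequence[str]]


@dataclass(frozen=True)
class FramePair:
    """Unordered pair in canonical order: ascending start, ties by frame_id."""

    frame_1: Frame
    frame_2: Frame

    def __post_init__(self) -> None:
        if self.frame_1.frame_id == self.frame_2.frame_id:
            raise ValueError("pair frames must have distinct IDs")


def enumerate_pairs(frames: list[Frame]) -> list[FramePair]:
    """All n·(n−1)/2 unordered pairs, canonically ordered."""
    ordered = sorted(frames, key=lambda f: (f.start, f.frame_id))
    return [
        FramePair(ordered[i], ordered[j])
        for i in range(len(ordered))
        for j in range(i + 1, len(ordered))
    ]


def _frame_json(frame: Frame) -> str:
    return json.dumps(
        {"frame_id": frame.frame_id, "entity_text": frame.entity_text, "attr": frame.attributes},
        ensure_ascii=False,
    )


def build_pair_context(doc: IEDocument, pair: FramePair, window: int = DEFAULT_WINDOW) -> dict[str, str]:
    """Template context for a pair prompt.

    ``roi_text`` is the span hull of the two frames widened by ``window``
    characters each side, clipped to the document.
    """
    lo = min(pair.frame_1.start, pair.frame_2.start)
    hi = max(pair.frame_1.end, pair.frame_2.end)
    roi = doc.text[max(0, lo - window) : min(len(doc.text), hi + window)]
    return {
        "frame_1": _frame_json(pair.frame_1),
        "frame_2": _frame_json(pair.frame_2),
        "roi_text": roi,
    }


_PAIR_PLACEHOLDERS = {"frame_1", "frame_2", "roi_text"}


def _check_template(template: str) -> None:
    extra = set(list_placeholders(template)) - _PAIR_PLACEHOLDERS
    if extra:
        raise ValueError(
            f"relation template placeholders must be within {sorted(_PAIR_PLACEHOLDERS)}; "
            f"unexpected: {sorted(extra)}"
        )


def _first_json_object(raw: str) -> dict | None:
    decoder = json.JSONDecoder()
    for idx, ch in enumerate(raw):
        if ch != "{":
            continue
        try:
            value, _ = decoder.raw_decode(raw, idx)
        except json.JSONDecodeError:
            continue
        if isinstance(value, dict):
            return value
    return None


def _parse_bool(value) -> bool | None:
    if isinstance(value, bool):
        return value
    if isinstance(value, str):
        low = value.strip().lower()
        if low == "true":
            return True
        if low == "false":
            return False
    return None


def extract_binary(
    doc: IEDocument,
    frames: list[Frame],
    template: str,
    engine: InferenceEngine,
    hook: BinaryHook | None = None,
    config: GenerationConfig | None = None,
    window: int = DEFAULT_WINDOW,
) -> list[Relation]:
    """Untyped relation detection over all frame pairs.

    For each pair the hook (if given) is consulted first; a falsy answer
    means no model call.  Otherwise the completion is parsed for a JSON
    object with boolean key ``"relation"`` (the strings "true"/"false" are
    accepted case-insensitively); unparseable completions skip the pair with
    a warning.
    """
    _check_template(template)
    relations: list[Relation] = []
    for pair in enumerate_pairs(frames):
        if hook is not None and not hook(pair.frame_1, pair.frame_2):
            continue
        prompt = render(template, build_pair_context(doc, pair, window))
        completion = engine.chat([user(prompt)], config)
        obj = _first_json_object(completion)
        answer = _parse_bool(obj.get("relation")) if obj else None
        if answer is None:
            logger.warning(
                "unparseable binary-relation answer for pair (%s,%s): %.80r",
                pair.frame_1.frame_id, pair.frame_2.frame_id, completion,
            )
            continue
        if answer:
            relations.append(Relation(pair.frame_1.frame_id, pair.frame_2.frame_id))
    return relations


def extract_multiclass(
    doc: IEDocument,
    frames: list[Frame],
    template: str,
    engine: InferenceEngine,
    hook: MulticlassHook,
    config: GenerationConfig | None = None,
    window: int = DEFAULT_WINDOW,
) -> list[Relation]:
    """Typed relation classification over all frame pairs.

    Pairs whose admissible type list is empty or exactly ``["No-relation"]``
    are decided without inference.  The completion is parsed for key
    ``"relation_type"``: ``"No-relation"`` stores nothing, an admissible type
    stores a typed relation, and anything outside the admissible list is
    discarded with a warning (closed-set enforcement).
    """
    _check_template(template)
    relations: list[Relation] = []
    for pair in enumerate_pairs(frames):
        admissible = list(hook(pair.frame_1, pair.frame_2))
        if not admissible or set(admissible) == {NO_RELATION}:
            continue
        prompt = render(template, build_pair_context(doc, pair, window))
        completion = engine.chat([user(prompt)], config)
        obj = _first_json_object(completion)
        answer = obj.get("relation_type") if obj else None
        if not isinstance(answer, str):
            logger.warning(
                "unparseable relation-type answer for pair (%s,%s): %.80r",
                pair.frame_1.frame_id, pair.frame_2.frame_id, completion,
            )
            continue
        if answer == NO_RELATION:
            continue
        if answer not in admissible:
            logger.warning(
                "answer %r not in admissible types %r for pair (%s,%s); discarded",
                answer, admissible, pair.frame_1.frame_id, pair.frame_2.frame_id,
            )
            continue
        relations.append(Relation(pair.frame_1.frame_id, pair.frame_2.frame_id, answer))
    return relations


def make_rule_hook(rules: list[dict], attr_key: str = "Type") -> MulticlassHook:
    """Build a multiclass hook from declarative rules.

    Each rule is ``{"type_1_attr": str, "type_2_attr": str, "types": [str]}``
    and matches a pair when the two frames' ``attr_key`` attribute values
    equal the two rule types in either order; the admissible list is the
    union of all matching rules' types, in rule order.  A pair matching no
    rule gets an empty list (skipped without inference).
    """
    def hook(frame_1: Frame, frame_2: Frame) -> list[str]:
        t1 = frame_1.attributes.get(attr_key)
        t2 = frame_2.attributes.get(attr_key)
        admissible: list[str] = []
        for rule in rules:
            a, b = rule["type_1_attr"], rule["type_2_attr"]
            if {t1, t2} == {a, b} or (t1 == t2 == a == b):
                for typ in rule["types"]:
                    if typ not in admissible:
                        admissible.append(typ)
        return admissible

    return hook


def make_binary_hook(rules: list[dict], attr_key: str = "Type") -> BinaryHook:
    """Binary variant: a pair is possible iff any non-"No-relation" type is
    admissible under the same rules."""
    multiclass = make_rule_hook(rules, attr_key)

    def hook(frame_1: Frame, frame_2: Frame) -> bool:
        return any(t != NO_RELATION for t in multiclass(frame_1, frame_2))

    return hook


def load_rules(path) -> list[dict]:
    """Load a rule set file: JSON list of rule objects (see make_rule_hook)."""
    with open(path, encoding="utf-8") as fh:
        rules = json.load(fh)
    if not isinstance(rules, list):
        raise ValueError("rules file must be a JSON list")
    for rule in rules:
        if not {"type_1_attr", "type_2_attr", "types"} <= set(rule):
            raise ValueError(f"rule missing required keys: {rule!r}")
    return rules
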