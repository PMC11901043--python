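"""Synthetic clinical notes with gold annotations, and scripted engines.

Real clinical corpora with medication/ADE annotations are access-restricted,
so the test bed is synthetic: each note is a sequence of single-sentence
medication statements ("Started aspirin 81 mg daily for migraine but
developed rash.") with gold frames for the drug (attributes ``Type``,
``Dosage``, ``Frequency``), an optional condition (``Type``, ``Assertion``)
and an optional adverse drug event (``Type``), plus gold ``Condition-Drug``
and ``ADE-Drug`` relations within the statement.

:func:`gen_script` then derives, from the gold annotations, the exact
completions a perfectly-behaved model would return for each extraction
prompt, optionally corrupted (dropped entities, malformed elements,
hallucinated entity texts) to exercise the post-processing discard rules.
Generation is a pure function of its spec: note sampling and corruption use
two independent random streams so corruption studies hold the corpus fixed.

Vocabulary terms contain no sentence terminators and no term is a substring
of another, so the sentence splitter's and the grounder's assumptions hold
by construction.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass

from .datamodel import Frame, IEDocument, Relation
from .frame_extraction import build_frame_prompt, split_sentences
from .engine import ScriptedEngine

__all__ = [
    "NoteSpec",
    "CorruptionSpec",
    "gen_corpus",
    "gen_script",
    "DEFAULT_TEMPLATE",
    "DEFAULT_RULES",
    "DRUGS",
    "CONDITIONS",
    "ADES",
]

DRUGS = [
    "aspirin", "metformin", "lisinopril", "atorvastatin", "omeprazole",
    "amlodipine", "metoprolol", "losartan", "gabapentin", "sertraline",
    "levothyroxine", "albuterol", "furosemide", "warfarin", "clopidogrel",
    "prednisone", "amoxicillin", "azithromycin", "ibuprofen", "tramadol",
]
DOSAGES = [
    "81 mg", "500 mg", "10 mg", "40 mg", "20 mg", "5 mg", "25 mg", "100 mg",
]
FREQUENCIES = [
    "once daily", "twice daily", "every morning", "at bedtime",
    "every 8 hours", "as needed",
]
CONDITIONS = [
    "hypertension", "hyperlipidemia", "migraine", "gastric reflux",
    "atrial fibrillation", "hypothyroidism", "asthma", "depression",
    "neuropathic pain", "bacterial sinusitis",
]
ADES = [
    "dry cough", "muscle aches", "dizziness", "skin rash",
    "stomach upset", "swollen ankles", "fatigue", "blurred vision",
]
ASSERTIONS = ["present", "absent", "possible"]

HALLUCINATED_TEXT = "zebrafish extract"  # never occurs in any note

DEFAULT_TEMPLATE = (
    "# Task description\n"
    "Extract every drug, condition, and adverse drug event (ADE) mention "
    "from the clinical text below.\n"
    "# Schema definition\n"
    "Each entity has an attribute Type in {Drug, Condition, ADE}. Drug "
    "entities also carry Dosage and Frequency; Condition entities carry "
    "Assertion in {present, absent, possible}.\n"
    "# Output format definition\n"
    'Answer with a JSON array of objects. Each object has the key '
    '"entity_text" holding the exact surface text, plus one key per '
    "attribute. Output [] if there are no entities.\n"
    "# Input\n"
    "{{input}}"
)

# Admissible relation types by frame Type pair for the synthetic schema.
DEFAULT_RULES = [
    {"type_1_attr": "Condition", "type_2_attr": "Drug", "types": ["Condition-Drug", "No-relation"]},
    {"type_1_attr": "ADE", "type_2_attr": "Drug", "types": ["ADE-Drug", "No-relation"]},
]


@dataclass(frozen=True)
class NoteSpec:
    """Conditions under which notes are generated.

    ``n_statements`` medication statements per note; each statement carries
    an indication with probability ``p_condition`` and an adverse event with
    probability ``p_ade``.
    """

    seed: int = 0
    n_statements: int = 4
    p_condition: float = 0.5
    p_ade: float = 0.3
    drugs: tuple[str, ...] = tuple(DRUGS)
    dosages: tuple[str, ...] = tuple(DOSAGES)
    frequencies: tuple[str, ...] = tuple(FREQUENCIES)
    conditions: tuple[str, ...] = tuple(CONDITIONS)
    assertions: tuple[str, ...] = tuple(ASSERTIONS)
    ades: tuple[str, ...] = tuple(ADES)

    def __post_init__(self) -> None:
        for p in (self.p_condition, self.p_ade):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        for vocab in (self.drugs, self.dosages, self.frequencies,
                      self.conditions, self.assertions, self.ades):
            if not vocab:
                raise ValueError("vocabulary lists must be non-empty")
        if self.n_statements < 1:
            raise ValueError("n_statements must be positive")


@dataclass(frozen=True)
class CorruptionSpec:
    """Response-corruption parameters for :func:`gen_script`.

    Per gold entity: dropped from the completion with probability
    ``p_drop``; followed by an extra element lacking ``entity_text`` with
    probability ``p_malform``; followed by an element naming out-of-text
    entity text with probability ``p_halluc``.  Corruption draws come from
    their own seeded stream, consumed in a fixed order regardless of the
    probabilities, so degradation is monotone in ``p_drop`` at fixed seed.
    """

    p_drop: float = 0.0
    p_malform: float = 0.0
    p_halluc: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_drop, self.p_malform, self.p_halluc):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")


def _make_statement(rng: random.Random, spec: NoteSpec) -> tuple[str, list[tuple[str, dict]], list[str]]:
    """One statement sentence.

    Returns (sentence text, entities as (surface, attributes) in order of
    appearance, relation types aligned with the non-drug entities).
    """
    drug = rng.choice(spec.drugs)
    dosage = rng.choice(spec.dosages)
    freq = rng.choice(spec.frequencies)
    with_condition = rng.random() < spec.p_condition
    with_ade = rng.random() < spec.p_ade
    # draw unconditionally to keep the stream aligned across specs
    condition = rng.choice(spec.conditions)
    assertion = rng.choice(spec.assertions)
    ade = rng.choice(spec.ades)

    sentence = f"Started {drug} {dosage} {freq}"
    entities: list[tuple[str, dict]] = [
        (drug, {"Type": "Drug", "Dosage": dosage, "Frequency": freq})
    ]
    rel_types: list[str] = []
    if with_condition:
        sentence += f" for {condition}"
        entities.append((condition, {"Type": "Condition", "Assertion": assertion}))
        rel_types.append("Condition-Drug")
    if with_ade:
        sentence += f" but developed {ade}"
        entities.append((ade, {"Type": "ADE"}))
        rel_types.append("ADE-Drug")
    sentence += "."
    return sentence, entities, rel_types


def gen_corpus(spec: NoteSpec, n_docs: int) -> list[IEDocument]:
    """Generate ``n_docs`` notes with gold frames and relations.

    Deterministic: output is a pure function of ``(spec, n_docs)``.
    """
    rng = random.Random(spec.seed)
    docs: list[IEDocument] = []
    for d in range(n_docs):
        parts: list[str] = []
        offset = 0
        frame_specs: list[tuple[int, int, str, dict]] = []
        relation_specs: list[tuple[int, int, str]] = []  # (frame idx, frame idx, type)
        for _ in range(spec.n_statements):
            sentence, entities, rel_types = _make_statement(rng, spec)
            if parts:
                offset += 1  # joining space
            cursor = offset
            drug_idx = None
            for k, (surface, attrs) in enumerate(entities):
                start = sentence.find(surface, cursor - offset) + offset
                end = start + len(surface)
                frame_specs.append((start, end, surface, attrs))
                idx = len(frame_specs) - 1
                if attrs["Type"] == "Drug":
                    drug_idx = idx
                cursor = end
            for k, rel_type in enumerate(rel_types):
                other_idx = drug_idx + 1 + k
                relation_specs.append((other_idx, drug_idx, rel_type))
            parts.append(sentence)
            offset += len(sentence)
        text = " ".join(parts)
        doc = IEDocument(doc_id=f"synth-{d:04d}", text=text)
        for i, (start, end, surface, attrs) in enumerate(frame_specs):
            doc.add_frame(
                Frame(frame_id=str(i), start=start, end=end,
                      entity_text=surface, attributes=dict(attrs))
            )
        for i1, i2, rel_type in relation_specs:
            doc.add_relation(Relation(str(i1), str(i2), rel_type))
        docs.append(doc)
    return docs


def _frames_in_region(doc: IEDocument, start: int, end: int) -> list[Frame]:
    return [f for f in doc.frames if start <= f.start and f.end <= end]


def _completion_for(frames: list[Frame], corruption: CorruptionSpec, rng: random.Random) -> str:
    elements: list[dict] = []
    for frame in frames:
        u_drop, u_malform, u_halluc = rng.random(), rng.random(), rng.random()
        if u_drop >= corruption.p_drop:
            elements.append({"entity_text": frame.entity_text, **frame.attributes})
        if u_malform < corruption.p_malform:
            elements.append({"Type": "Noise"})
        if u_halluc < corruption.p_halluc:
            elements.append({"entity_text": HALLUCINATED_TEXT})
    return json.dumps(elements, ensure_ascii=False)


def gen_script(
    docs: list[IEDocument],
    template: str = DEFAULT_TEMPLATE,
    corruption: CorruptionSpec | None = None,
    granularity: str = "per_sentence",
    few_shot: list[dict] | None = None,
) -> ScriptedEngine:
    """Derive a scripted engine that answers extraction prompts from gold.

    For every document (``whole_doc``) or sentence (``per_sentence``) the
    gold frames of that region are encoded as the JSON-array completion the
    extractor expects, keyed by the exact prompt the extractor will send.
    """
    if granularity not in ("whole_doc", "per_sentence"):
        raise ValueError("granularity must be 'whole_doc' or 'per_sentence'")
    corruption = corruption or CorruptionSpec()
    rng = random.Random(corruption.seed)
    exact: dict[str, str] = {}
    for doc in docs:
        if granularity == "whole_doc":
            regions = [(doc.text, 0, len(doc.text))]
        else:
            regions = [(s.text, s.start, s.end) for s in split_sentences(doc.text)]
        for region_text, start, end in regions:
            prompt = build_frame_prompt(template, region_text, few_shot)
            completion = _completion_for(
                _frames_in_region(doc, start, end), corruption, rng
            )
            exact[prompt] = completion
    return ScriptedEngine(exact=exact)
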