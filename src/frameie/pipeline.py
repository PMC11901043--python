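"""Runnable pipelines: corpus-level extraction and evaluation.

These functions are the programmatic counterparts of the CLI subcommands:
:func:`run_extract` reads a JSON-lines corpus, applies a configured frame
extractor (and optionally a relation extractor) to every document with one
shared engine, and writes the annotated corpus back out;
:func:`run_evaluate` scores a predicted corpus against a gold corpus.

All randomness flows from ``RunConfig.seed``; with a scripted engine the
whole pipeline is deterministic and two identical runs produce byte-identical
output files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import frame_extraction, relation_extraction
from .datamodel import IEDocument, read_jsonl, write_jsonl
from .engine import EndpointEngine, GenerationConfig, InferenceEngine, ScriptedEngine
from .evaluation import (
    EvalCounts,
    MatchMode,
    evaluate_attributes,
    evaluate_relations,
    match_frames,
    matching_by_id,
)
from .templating import load_few_shot, load_template

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_extract", "run_evaluate"]

EXTRACTORS = ("basic", "review", "sentence")
RELATION_MODES = ("none", "binary", "multiclass")


@dataclass
class RunConfig:
    """Configuration of one extraction run.

    Exactly one engine must be given: ``script_path`` (scripted engine) or
    ``endpoint_url`` + ``model`` (HTTP chat endpoint).
    """

    template_path: str
    script_path: str | None = None
    endpoint_url: str | None = None
    model: str | None = None
    api_key_env: str | None = None
    few_shot_path: str | None = None
    extractor: str = "sentence"
    review_mode: str = "addition"
    relation: str = "none"
    relation_template_path: str | None = None
    hook_rules_path: str | None = None
    window: int = relation_extraction.DEFAULT_WINDOW
    temperature: float = 0.0
    max_tokens: int = 1024
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.script_path is None) == (self.endpoint_url is None):
            raise ValueError("exactly one of script_path or endpoint_url must be set")
        if self.extractor not in EXTRACTORS:
            raise ValueError(f"extractor must be one of {EXTRACTORS}")
        if self.relation not in RELATION_MODES:
            raise ValueError(f"relation must be one of {RELATION_MODES}")
        if self.relation != "none" and not self.relation_template_path:
            raise ValueError("relation extraction requires relation_template_path")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))

    def build_engine(self) -> InferenceEngine:
        if self.script_path is not None:
            return ScriptedEngine.from_file(self.script_path)
        return EndpointEngine(self.endpoint_url, self.model or "", self.api_key_env)


class _WarningCounter(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.count = 0

    def emit(self, record: logging.LogRecord) -> None:
        self.count += 1


def _extract_frames(doc: IEDocument, config: RunConfig, template: str,
                    engine: InferenceEngine, few_shot, gen: GenerationConfig):
    if config.extractor == "basic":
        return frame_extraction.extract_basic(doc.text, template, engine, few_shot, gen)
    if config.extractor == "review":
        return frame_extraction.extract_review(
            doc.text, template, engine, few_shot, gen, mode=config.review_mode
        )
    return frame_extraction.extract_sentence(doc.text, template, engine, few_shot, gen)


def run_extract(config: RunConfig, in_path: str | Path, out_path: str | Path,
                engine: InferenceEngine | None = None) -> dict:
    """Run extraction over a corpus file.

    Returns a summary record ``{docs, frames, relations, engine_calls,
    warnings}``.  An ``engine`` may be passed in directly (e.g. a prebuilt
    scripted engine); otherwise it is constructed from the config.
    """
    engine = engine or config.build_engine()
    template = load_template(config.template_path)
    few_shot = load_few_shot(config.few_shot_path) if config.few_shot_path else None
    gen = GenerationConfig(temperature=config.temperature, max_tokens=config.max_tokens)

    hook = None
    rel_template = None
    if config.relation != "none":
        rel_template = load_template(config.relation_template_path)
        rules = relation_extraction.load_rules(config.hook_rules_path) if config.hook_rules_path else None
        if config.relation == "multiclass":
            if rules is None:
                raise ValueError("multiclass relation extraction requires hook_rules_path")
            hook = relation_extraction.make_rule_hook(rules)
        elif rules is not None:
            hook = relation_extraction.make_binary_hook(rules)

    counter = _WarningCounter()
    pkg_logger = logging.getLogger("frameie")
    pkg_logger.addHandler(counter)
    try:
        out_docs: list[IEDocument] = []
        n_frames = n_relations = 0
        for doc in read_jsonl(in_path):
            annotated = IEDocument(doc_id=doc.doc_id, text=doc.text)
            for frame in _extract_frames(doc, config, template, engine, few_shot, gen):
                annotated.add_frame(frame)
            if config.relation == "binary":
                rels = relation_extraction.extract_binary(
                    annotated, annotated.frames, rel_template, engine, hook, gen, config.window
                )
            elif config.relation == "multiclass":
                rels = relation_extraction.extract_multiclass(
                    annotated, annotated.frames, rel_template, engine, hook, gen, config.window
                )
            else:
                rels = []
            for rel in rels:
                annotated.add_relation(rel)
            n_frames += len(annotated.frames)
            n_relations += len(annotated.relations)
            out_docs.append(annotated)
        write_jsonl(out_docs, out_path)
    finally:
        pkg_logger.removeHandler(counter)
    return {
        "docs": len(out_docs),
        "frames": n_frames,
        "relations": n_relations,
        "engine_calls": len(getattr(engine, "call_log", [])),
        "warnings": counter.count,
    }


def _counts_record(c: EvalCounts) -> dict:
    return {
        "tp": c.tp, "fp": c.fp, "fn": c.fn,
        "precision": c.precision, "recall": c.recall, "f1": c.f1,
    }


def run_evaluate(
    gold_path: str | Path,
    pred_path: str | Path,
    mode: MatchMode | str = MatchMode.STRICT,
    label_key: str | None = None,
    attr_keys: list[str] | None = None,
) -> dict:
    """Score a predicted corpus against gold, micro-averaged over documents.

    Documents are paired by ``doc_id``; the two corpora must contain the
    same IDs.  Relations are scored whenever the gold corpus has any,
    using the same frame matching.
    """
    gold_docs = {d.doc_id: d for d in read_jsonl(gold_path)}
    pred_docs = {d.doc_id: d for d in read_jsonl(pred_path)}
    if set(gold_docs) != set(pred_docs):
        missing = set(gold_docs) ^ set(pred_docs)
        raise ValueError(f"doc_id mismatch between gold and pred: {sorted(missing)[:5]}")

    mode = MatchMode(mode)
    per_doc: dict[str, dict] = {}
    micro = EvalCounts(0, 0, 0)
    micro_rel = EvalCounts(0, 0, 0)
    micro_attrs: dict[str, EvalCounts] = {k: EvalCounts(0, 0, 0) for k in (attr_keys or [])}
    any_gold_relations = any(d.relations for d in gold_docs.values())
    for doc_id in sorted(gold_docs):
        gold, pred = gold_docs[doc_id], pred_docs[doc_id]
        counts = match_frames(gold.frames, pred.frames, mode, label_key)
        micro += counts
        entry = {"frames": _counts_record(counts)}
        if attr_keys:
            attr_counts = evaluate_attributes(gold.frames, pred.frames, mode, attr_keys, label_key)
            for k, c in attr_counts.items():
                micro_attrs[k] += c
            entry["attributes"] = {k: _counts_record(c) for k, c in attr_counts.items()}
        if any_gold_relations:
            frame_map = matching_by_id(gold.frames, pred.frames, mode, label_key)
            rel_counts = evaluate_relations(gold.relations, pred.relations, frame_map)
            micro_rel += rel_counts
            entry["relations"] = _counts_record(rel_counts)
        per_doc[doc_id] = entry

    report = {
        "mode": mode.value,
        "label_key": label_key,
        "micro": {"frames": _counts_record(micro)},
        "per_doc": per_doc,
    }
    if attr_keys:
        report["micro"]["attributes"] = {k: _counts_record(c) for k, c in micro_attrs.items()}
    if any_gold_relations:
        report["micro"]["relations"] = _counts_record(micro_rel)
    return report
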