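"""Strict/relaxed evaluation of frames, attributes, and relations.

The scoring conventions follow the clinical NER benchmark tradition:

* **strict** — a predicted frame counts as a true positive only with an
  identical ``(start, end)`` span and equal label;
* **relaxed** (synonymously *lenient*) — any span overlap of at least one
  character with equal label suffices.

Scoring computes a *maximum* one-to-one matching between gold and predicted
frames under the chosen compatibility relation (via Hopcroft–Karp bipartite
matching), so results do not depend on frame order and no greedy pairing
artifacts occur.  Attribute evaluation scores matched frame pairs by exact
string equality of trimmed values; relation evaluation maps predicted frame
IDs onto gold frame IDs through the frame matching and requires the same
unordered pair and type.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from .datamodel import Frame, Relation

__all__ = [
    "MatchMode",
    "EvalCounts",
    "UnknownLabelKeyError",
    "frame_matching",
    "match_frames",
    "matching_by_id",
    "evaluate_attributes",
    "evaluate_relations",
]


class MatchMode(str, Enum):
    STRICT = "strict"
    RELAXED = "relaxed"


class UnknownLabelKeyError(KeyError):
    """label_key names an attribute absent from every frame."""


@dataclass(frozen=True)
class EvalCounts:
    """TP/FP/FN with derived precision, recall, and F1.

    Zero-denominator metrics are defined as 0.0.
    """

    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


def _labels(frames: Iterable[Frame], label_key: str | None) -> list:
    return [f.attributes.get(label_key) if label_key else None for f in frames]


def _compatible(g: Frame, p: Frame, mode: MatchMode, g_label, p_label) -> bool:
    if g_label != p_label:
        return False
    if mode == MatchMode.STRICT:
        return (g.start, g.end) == (p.start, p.end)
    return max(g.start, p.start) < min(g.end, p.end)


def _check_label_key(gold: list[Frame], pred: list[Frame], label_key: str | None) -> None:
    frames = list(gold) + list(pred)
    if label_key and frames and all(label_key not in f.attributes for f in frames):
        raise UnknownLabelKeyError(f"attribute {label_key!r} absent from all frames")


def frame_matching(
    gold: list[Frame],
    pred: list[Frame],
    mode: MatchMode | str = MatchMode.STRICT,
    label_key: str | None = None,
) -> list[tuple[int, int]]:
    """Maximum one-to-one matching as (gold index, pred index) pairs."""
    mode = MatchMode(mode)
    _check_label_key(gold, pred, label_key)
    if not gold or not pred:
        return []
    g_labels = _labels(gold, label_key)
    p_labels = _labels(pred, label_key)
    rows, cols = [], []
    for i, g in enumerate(gold):
        for j, p in enumerate(pred):
            if _compatible(g, p, mode, g_labels[i], p_labels[j]):
                rows.append(i)
                cols.append(j)
    if not rows:
        return []
    graph = csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(len(gold), len(pred))
    )
    col_of_row = maximum_bipartite_matching(graph, perm_type="column")
    return [(i, int(j)) for i, j in enumerate(col_of_row) if j >= 0]


def match_frames(
    gold: list[Frame],
    pred: list[Frame],
    mode: MatchMode | str = MatchMode.STRICT,
    label_key: str | None = None,
) -> EvalCounts:
    """Frame-level evaluation counts under the chosen match mode."""
    pairs = frame_matching(gold, pred, mode, label_key)
    tp = len(pairs)
    return EvalCounts(tp=tp, fp=len(pred) - tp, fn=len(gold) - tp)


def matching_by_id(
    gold: list[Frame],
    pred: list[Frame],
    mode: MatchMode | str = MatchMode.STRICT,
    label_key: str | None = None,
) -> dict[str, str]:
    """Frame matching expressed as pred frame_id -> gold frame_id."""
    return {
        pred[j].frame_id: gold[i].frame_id
        for i, j in frame_matching(gold, pred, mode, label_key)
    }


def evaluate_attributes(
    gold: list[Frame],
    pred: list[Frame],
    mode: MatchMode | str,
    attr_keys: list[str],
    label_key: str | None = None,
) -> dict[str, EvalCounts]:
    """Per-attribute evaluation over a frame matching.

    For each key: a matched frame pair where both values are equal
    (case-sensitive, after trimming) is a TP; a matched pair with unequal
    values counts FP and FN; a frame carrying the key on one side only, or
    left unmatched, counts toward that side's error.
    """
    pairs = frame_matching(gold, pred, mode, label_key)
    matched_g = {i for i, _ in pairs}
    matched_p = {j for _, j in pairs}
    out: dict[str, EvalCounts] = {}
    for key in attr_keys:
        tp = fp = fn = 0
        for i, j in pairs:
            gv = gold[i].attributes.get(key)
            pv = pred[j].attributes.get(key)
            if gv is None and pv is None:
                continue
            if gv is not None and pv is not None and gv.strip() == pv.strip():
                tp += 1
            else:
                if pv is not None:
                    fp += 1
                if gv is not None:
                    fn += 1
        fn += sum(
            1 for i, g in enumerate(gold) if i not in matched_g and key in g.attributes
        )
        fp += sum(
            1 for j, p in enumerate(pred) if j not in matched_p and key in p.attributes
        )
        out[key] = EvalCounts(tp=tp, fp=fp, fn=fn)
    return out


def evaluate_relations(
    gold_rels: list[Relation],
    pred_rels: list[Relation],
    frame_map: Mapping[str, str],
) -> EvalCounts:
    """Relation evaluation given a pred→gold frame-ID mapping.

    A predicted relation is a TP iff both its frames map to gold frames that
    are joined by a gold relation of the same type (order-insensitive); each
    gold relation can absorb at most one prediction.
    """
    remaining: list[Relation] = list(gold_rels)
    tp = 0
    for rel in pred_rels:
        g1 = frame_map.get(rel.frame_1_id)
        g2 = frame_map.get(rel.frame_2_id)
        if g1 is None or g2 is None:
            continue
        key = frozenset((g1, g2))
        hit = next(
            (
                g
                for g in remaining
                if g.id_pair() == key and g.relation_type == rel.relation_type
            ),
            None,
        )
        if hit is not None:
            remaining.remove(hit)
            tp += 1
    return EvalCounts(tp=tp, fp=len(pred_rels) - tp, fn=len(remaining))
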