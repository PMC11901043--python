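"""Containers for extracted information.

A *frame* is one extracted entity mention: an identifier, a character span
into the source text, the surface text of the mention, and a free-form
attribute map (e.g. ``Type=Drug``, ``Dosage=81 mg``).  A *relation* links two
frames of the same document, optionally with a type string.  An
:class:`IEDocument` bundles a document's text with its frames and relations
and is the unit of storage, validation, and visualization.

Spans are 0-based, half-open ``[start, end)`` and counted in Unicode code
points.  Frame IDs are unique within a document; by convention the
extractors assign decimal strings ``"0", "1", ...`` in extraction order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

__all__ = [
    "Frame",
    "Relation",
    "IEDocument",
    "ValidationReport",
    "DataModelError",
    "DuplicateIDError",
    "SpanOutOfBoundsError",
    "TextMismatchError",
    "DanglingFrameIDError",
    "SelfRelationError",
    "SchemaError",
    "read_jsonl",
    "write_jsonl",
]


class DataModelError(ValueError):
    """Base class for document-integrity errors."""


class DuplicateIDError(DataModelError):
    pass


class SpanOutOfBoundsError(DataModelError):
    pass


class TextMismatchError(DataModelError):
    pass


class DanglingFrameIDError(DataModelError):
    pass


class SelfRelationError(DataModelError):
    pass


class SchemaError(DataModelError):
    """A serialized record is missing required keys or has wrong types."""


@dataclass
class Frame:
    """One extracted entity mention.

    Attributes
    ----------
    frame_id : str
        Identifier, unique within its document.
    start, end : int
        Character span, 0-based half-open, in Unicode code points.
    entity_text : str
        Surface text of the mention; for grounded frames this equals
        ``document.text[start:end]``.
    attributes : dict[str, str]
        Free-form entity attributes (e.g. ``{"Type": "Drug"}``).
    """

    frame_id: str
    start: int
    end: int
    entity_text: str
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.start, int) or not isinstance(self.end, int):
            raise SchemaError("frame span offsets must be integers")
        if not (0 <= self.start < self.end):
            raise SpanOutOfBoundsError(
                f"invalid span ({self.start}, {self.end}): need 0 <= start < end"
            )
        if not self.entity_text:
            raise SchemaError("entity_text must be non-empty")

    def overlaps(self, other: "Frame") -> bool:
        return max(self.start, other.start) < min(self.end, other.end)

    def to_record(self) -> dict:
        return {
            "frame_id": self.frame_id,
            "start": self.start,
            "end": self.end,
            "entity_text": self.entity_text,
            "attr": dict(self.attributes),
        }

    @classmethod
    def from_record(cls, rec: dict) -> "Frame":
        try:
            return cls(
                frame_id=str(rec["frame_id"]),
                start=rec["start"],
                end=rec["end"],
                entity_text=rec["entity_text"],
                attributes={str(k): str(v) for k, v in rec.get("attr", {}).items()},
            )
        except KeyError as exc:
            raise SchemaError(f"frame record missing key {exc}") from exc


@dataclass
class Relation:
    """An undirected link between two frames; direction, if any, is encoded
    in the type string (e.g. ``"ADE-Drug"``).  ``relation_type=None`` means an
    untyped (binary) relation."""

    frame_1_id: str
    frame_2_id: str
    relation_type: str | None = None

    def __post_init__(self) -> None:
        if self.frame_1_id == self.frame_2_id:
            raise SelfRelationError(f"relation links frame {self.frame_1_id!r} to itself")

    def id_pair(self) -> frozenset:
        return frozenset((self.frame_1_id, self.frame_2_id))

    def to_record(self) -> dict:
        return {
            "frame_1_id": self.frame_1_id,
            "frame_2_id": self.frame_2_id,
            "relation_type": self.relation_type,
        }

    @classmethod
    def from_record(cls, rec: dict) -> "Relation":
        try:
            return cls(
                frame_1_id=str(rec["frame_1_id"]),
                frame_2_id=str(rec["frame_2_id"]),
                relation_type=rec.get("relation_type"),
            )
        except KeyError as exc:
            raise SchemaError(f"relation record missing key {exc}") from exc


@dataclass
class ValidationReport:
    """Result of :meth:`IEDocument.validate`.

    ``overlaps`` lists unordered frame-ID pairs whose spans intersect but
    are not redundant; ``redundant`` lists pairs with identical
    ``(start, end, entity_text)``; ``dangling_relations`` lists indices of
    relations referencing missing frame IDs.  An empty report means the
    document passes all checks.
    """

    overlaps: list[tuple[str, str]] = field(default_factory=list)
    redundant: list[tuple[str, str]] = field(default_factory=list)
    dangling_relations: list[int] = field(default_factory=list)

    def ok(self) -> bool:
        return not (self.overlaps or self.redundant or self.dangling_relations)


@dataclass
class IEDocument:
    """A self-contained document: text plus frames plus relations.

    Frames keep insertion order.  Mutation goes through :meth:`add_frame`
    and :meth:`add_relation`, which enforce the integrity rules.
    """

    doc_id: str
    text: str
    frames: list[Frame] = field(default_factory=list)
    relations: list[Relation] = field(default_factory=list)

    # -- construction -----------------------------------------------------

    def add_frame(self, frame: Frame, strict: bool = True) -> "IEDocument":
        """Append ``frame``.

        Duplicate frame IDs are always rejected.  With ``strict`` (the
        default) a span outside the text or an ``entity_text`` that is not
        the text slice is rejected too.  Overlap with an existing frame is
        legitimate in clinical annotation (nested entities) and is only
        logged as a warning.
        """
        if any(f.frame_id == frame.frame_id for f in self.frames):
            raise DuplicateIDError(f"frame_id {frame.frame_id!r} already in document {self.doc_id!r}")
        if strict:
            if frame.end > len(self.text):
                raise SpanOutOfBoundsError(
                    f"span ({frame.start}, {frame.end}) exceeds text length {len(self.text)}"
                )
            slice_ = self.text[frame.start : frame.end]
            if slice_ != frame.entity_text:
                raise TextMismatchError(
                    f"entity_text {frame.entity_text!r} != text slice {slice_!r}"
                )
        for other in self.frames:
            if frame.overlaps(other):
                logger.warning(
                    "frame %r (%d,%d) overlaps frame %r (%d,%d) in doc %r",
                    frame.frame_id, frame.start, frame.end,
                    other.frame_id, other.start, other.end, self.doc_id,
                )
        self.frames.append(frame)
        return self

    def add_relation(self, rel: Relation) -> "IEDocument":
        """Append ``rel`` after checking both frame IDs resolve."""
        ids = {f.frame_id for f in self.frames}
        for fid in (rel.frame_1_id, rel.frame_2_id):
            if fid not in ids:
                raise DanglingFrameIDError(f"relation references missing frame_id {fid!r}")
        self.relations.append(rel)
        return self

    def get_frame(self, frame_id: str) -> Frame:
        for f in self.frames:
            if f.frame_id == frame_id:
                return f
        raise DanglingFrameIDError(f"no frame with id {frame_id!r}")

    # -- validation -------------------------------------------------------

    def validate(self) -> ValidationReport:
        """All-pairs span check plus relation resolution.

        Each offending unordered pair is reported exactly once; redundant
        pairs (identical span and text) are not repeated under overlaps.
        """
        report = ValidationReport()
        for i, a in enumerate(self.frames):
            for b in self.frames[i + 1 :]:
                if (a.start, a.end, a.entity_text) == (b.start, b.end, b.entity_text):
                    report.redundant.append((a.frame_id, b.frame_id))
                elif a.overlaps(b):
                    report.overlaps.append((a.frame_id, b.frame_id))
        ids = {f.frame_id for f in self.frames}
        for idx, rel in enumerate(self.relations):
            if rel.frame_1_id not in ids or rel.frame_2_id not in ids:
                report.dangling_relations.append(idx)
        return report

    # -- serialization ----------------------------------------------------

    def to_record(self) -> dict:
        return {
            "doc_id": self.doc_id,
            "text": self.text,
            "frames": [f.to_record() for f in self.frames],
            "relations": [r.to_record() for r in self.relations],
        }

    @classmethod
    def from_record(cls, rec: dict) -> "IEDocument":
        """Build a document from a plain record.

        Unknown extra keys are ignored (forward compatibility).  Frames are
        re-added through :meth:`add_frame` in non-strict mode so insertion
        order and ID uniqueness are preserved without requiring grounding.
        """
        if not isinstance(rec, dict):
            raise SchemaError("document record must be an object")
        for key, typ in (("doc_id", str), ("text", str)):
            if key not in rec:
                raise SchemaError(f"document record missing key {key!r}")
            if not isinstance(rec[key], typ):
                raise SchemaError(f"document key {key!r} must be {typ.__name__}")
        doc = cls(doc_id=rec["doc_id"], text=rec["text"])
        for frec in rec.get("frames", []):
            doc.add_frame(Frame.from_record(frec), strict=False)
        for rrec in rec.get("relations", []):
            doc.add_relation(Relation.from_record(rrec))
        return doc

    def copy(self) -> "IEDocument":
        return IEDocument(
            doc_id=self.doc_id,
            text=self.text,
            frames=[replace(f, attributes=dict(f.attributes)) for f in self.frames],
            relations=[replace(r) for r in self.relations],
        )


def write_jsonl(docs: Iterable[IEDocument], path: str | Path) -> None:
    """Write documents as a UTF-8 JSON-lines corpus, one object per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(json.dumps(doc.to_record(), ensure_ascii=False) + "\n")


def read_jsonl(path: str | Path) -> Iterator[IEDocument]:
    """Yield documents from a JSON-lines corpus file."""
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise SchemaError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
            yield IEDocument.from_record(rec)
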