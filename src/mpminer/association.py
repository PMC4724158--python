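"""Grouping of patent text into experimental sections and association of
melting-point mentions with chemical entities.

Chemical named-entity recognition is an *input* here: documents arrive with
entity spans (and, where resolved, SMILES) already annotated, either by an
external NER tool or by the synthetic corpus generator.  Two binding modes
are implemented:

* **explicit** — the melting point sits in a bracketed group immediately
  after the entity, e.g. ``benzamide (m.p. 101–102 °C)``;
* **implicit** — the melting point closes the characterization sentence at
  the end of an experimental section, and is assumed to belong to the
  compound being synthesized in that section.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .grammar import MPMention, NormalizedMP, flag_suspicious, normalize, parse_all

logger = logging.getLogger(__name__)

__all__ = [
    "Block",
    "Entity",
    "AnnotatedDocument",
    "Section",
    "CompoundMPRecord",
    "UnassociatedMention",
    "group_sections",
    "associate",
    "extract_records",
    "DEFAULT_WINDOW",
]

DEFAULT_WINDOW = 80  # max characters between entity end and opening bracket


@dataclass(frozen=True)
class Block:
    kind: str  # "heading" | "paragraph"
    text: str
    paragraph_number: Optional[int] = None


@dataclass(frozen=True)
class Entity:
    block_index: int
    char_span: Tuple[int, int]
    label: str
    smiles: Optional[str] = None


@dataclass
class AnnotatedDocument:
    doc_id: str
    blocks: List[Block]
    entities: List[Entity] = field(default_factory=list)

    def validate(self) -> None:
        seen = set()
        for b in self.blocks:
            if b.paragraph_number is not None:
                if b.paragraph_number in seen:
                    raise ValueError(
                        f"duplicate paragraph number {b.paragraph_number}")
                seen.add(b.paragraph_number)
        for e in self.entities:
            text = self.blocks[e.block_index].text
            s, t = e.char_span
            if not (0 <= s <= t <= len(text)):
                raise ValueError(f"entity span {e.char_span} outside block")

    # -- JSON document schema -------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "doc_id": self.doc_id,
            "blocks": [
                {"kind": b.kind, "paragraph_number": b.paragraph_number,
                 "text": b.text} for b in self.blocks],
            "entities": [
                {"block_index": e.block_index, "char_span": list(e.char_span),
                 "label": e.label, "smiles": e.smiles} for e in self.entities],
        })

    @classmethod
    def from_json(cls, data: str) -> "AnnotatedDocument":
        d = json.loads(data)
        return cls(
            doc_id=d["doc_id"],
            blocks=[Block(kind=b["kind"], text=b["text"],
                          paragraph_number=b.get("paragraph_number"))
                    for b in d["blocks"]],
            entities=[Entity(block_index=e["block_index"],
                             char_span=tuple(e["char_span"]),
                             label=e["label"], smiles=e.get("smiles"))
                      for e in d.get("entities", [])],
        )


@dataclass(frozen=True)
class Section:
    """A heading (or none) plus the paragraph blocks that follow it."""

    heading_index: Optional[int]
    paragraph_indices: Tuple[int, ...]


@dataclass(frozen=True)
class CompoundMPRecord:
    smiles: str
    mp: NormalizedMP
    doc_id: str
    paragraph_number: Optional[int]
    association_kind: str  # "explicit" | "implicit"


@dataclass(frozen=True)
class UnassociatedMention:
    mention: MPMention
    block_index: int
    reason: str


def group_sections(doc: AnnotatedDocument) -> List[Section]:
    """Partition the document's blocks into experimental sections.

    Each heading opens a section holding every paragraph up to the next
    heading; paragraphs before the first heading form one anonymous section.
    """
    sections: List[Section] = []
    heading: Optional[int] = None
    paragraphs: List[int] = []
    started = False
    for i, block in enumerate(doc.blocks):
        if block.kind == "heading":
            if started or paragraphs:
                sections.append(Section(heading, tuple(paragraphs)))
            heading, paragraphs, started = i, [], True
        else:
            paragraphs.append(i)
    if started or paragraphs:
        sections.append(Section(heading, tuple(paragraphs)))
    return sections


def _inside_bracket(text: str, pos: int) -> Optional[int]:
    """Position of the ``(`` enclosing ``pos``, or None."""
    depth = 0
    for i in range(pos - 1, -1, -1):
        c = text[i]
        if c == ")":
            depth += 1
        elif c == "(":
            if depth == 0:
                return i
            depth -= 1
    return None


def _target_entity(doc: AnnotatedDocument, section: Section) -> Optional[Entity]:
    """The compound a section synthesizes: the last structure-bearing entity
    of the heading, else the first structure-bearing entity of the section."""
    if section.heading_index is not None:
        in_heading = [e for e in doc.entities
                      if e.block_index == section.heading_index and e.smiles]
        if in_heading:
            return max(in_heading, key=lambda e: e.char_span[0])
    indices = set(section.paragraph_indices)
    if section.heading_index is not None:
        indices.add(section.heading_index)
    candidates = [e for e in doc.entities if e.block_index in indices and e.smiles]
    if candidates:
        return min(candidates, key=lambda e: (e.block_index, e.char_span[0]))
    return None


def associate(
    doc: AnnotatedDocument,
    section: Section,
    mentions: Optional[Sequence[Tuple[int, MPMention]]] = None,
    window: int = DEFAULT_WINDOW,
) -> Tuple[List[CompoundMPRecord], List[UnassociatedMention]]:
    """Bind each melting-point mention in a section to a chemical entity.

    Explicit bracket-proximity binding is always preferred; a mention in the
    section's final paragraph falls back to the section's target compound.
    Returns bound records and the mentions left unbound with a reason.
    """
    if mentions is None:
        mentions = [(bi, m) for bi in section.paragraph_indices
                    for m in parse_all(doc.blocks[bi].text)]
    records: List[CompoundMPRecord] = []
    leftovers: List[UnassociatedMention] = []
    last_para = section.paragraph_indices[-1] if section.paragraph_indices else None
    target = _target_entity(doc, section)

    for block_index, mention in mentions:
        text = doc.blocks[block_index].text
        bound: Optional[Entity] = None
        kind = "explicit"
        bracket = _inside_bracket(text, mention.char_span[0])
        if bracket is not None:
            candidates = [
                e for e in doc.entities
                if e.block_index == block_index and e.smiles
                and e.char_span[1] <= bracket
                and bracket - e.char_span[1] <= window
            ]
            if len(candidates) > 1:
                logger.warning(
                    "doc %s: %d explicit candidates for mention %r; "
                    "binding nearest preceding entity",
                    doc.doc_id, len(candidates), mention.raw_text)
            if candidates:
                bound = max(candidates, key=lambda e: e.char_span[1])
        if bound is None and block_index == last_para and target is not None:
            bound, kind = target, "implicit"

        if bound is None:
            reason = ("no candidate" if target is None
                      else "not in final paragraph")
            leftovers.append(UnassociatedMention(mention, block_index, reason))
            continue
        records.append(CompoundMPRecord(
            smiles=bound.smiles,
            mp=flag_suspicious(normalize(mention)),
            doc_id=doc.doc_id,
            paragraph_number=doc.blocks[block_index].paragraph_number,
            association_kind=kind,
        ))
    return records, leftovers


def extract_records(
    doc: AnnotatedDocument, window: int = DEFAULT_WINDOW
) -> Tuple[List[CompoundMPRecord], List[UnassociatedMention]]:
    """Full document pipeline: section grouping, parsing and association."""
    doc.validate()
    records: List[CompoundMPRecord] = []
    leftovers: List[UnassociatedMention] = []
    for section in group_sections(doc):
        r, u = associate(doc, section, window=window)
        records.extend(r)
        leftovers.extend(u)
    return records, leftovers
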