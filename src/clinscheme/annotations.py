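"""In-memory model of one annotated document.

Annotations follow the BRAT standoff model: text-bound annotations
(:class:`TextBound`, serialized as T-lines) cover both entity mentions and
text-anchored attribute markers — which of the two a given T-line is gets
decided against a scheme's inventories at validation time, not at parse
time.  :class:`Attribute` (A-lines) carries valued attributes and boolean
flags; :class:`Relation` (R-lines) carries typed directed links.

Offsets are 0-based, half-open, character (not byte) offsets into the
document's Unicode text; discontinuous mentions are ordered lists of
fragments.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "TextSpan",
    "TextBound",
    "Attribute",
    "Relation",
    "AnnotatedDocument",
    "DocumentInvariantError",
    "ann_id_key",
]

_ID_RE = re.compile(r"^([A-Za-z#*]+)(\d+)$")


def ann_id_key(ann_id: str) -> tuple[str, int]:
    """Sort key ordering annotation ids numerically within each prefix group."""
    m = _ID_RE.match(ann_id)
    if m:
        return (m.group(1), int(m.group(2)))
    return (ann_id, -1)


class DocumentInvariantError(ValueError):
    """A document violates a structural invariant."""


@dataclass(frozen=True, order=True)
class TextSpan:
    """Ordered, non-overlapping character fragments, 0-based half-open."""

    fragments: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.fragments:
            raise DocumentInvariantError("span has no fragments")
        prev_end = None
        for start, end in self.fragments:
            if start >= end:
                raise DocumentInvariantError(f"empty fragment ({start}, {end})")
            if prev_end is not None and start < prev_end:
                raise DocumentInvariantError("fragments overlap or are unsorted")
            prev_end = end

    @classmethod
    def single(cls, start: int, end: int) -> "TextSpan":
        return cls(fragments=((start, end),))

    @property
    def start(self) -> int:
        return self.fragments[0][0]

    @property
    def end(self) -> int:
        return self.fragments[-1][1]

    def covered_characters(self) -> set[int]:
        out: set[int] = set()
        for start, end in self.fragments:
            out.update(range(start, end))
        return out

    def extract(self, text: str) -> str:
        """Covered text, fragments joined with a single space (BRAT convention)."""
        return " ".join(text[s:e] for s, e in self.fragments)

    def shifted(self, delta: int) -> "TextSpan":
        return TextSpan(tuple((s + delta, e + delta) for s, e in self.fragments))


@dataclass(frozen=True)
class TextBound:
    """A text-bound annotation: an entity mention or an anchored-attribute marker."""

    id: str
    type: str
    span: TextSpan
    surface: str


@dataclass(frozen=True)
class Attribute:
    """A valued attribute or boolean flag attached to another annotation.

    ``value`` is None for binary flags (e.g. an abbreviation marker).
    """

    id: str
    name: str
    target: str
    value: str | None = None


@dataclass(frozen=True)
class Relation:
    """A typed directed link between two text-bound annotations."""

    id: str
    name: str
    source: str
    target: str


@dataclass
class AnnotatedDocument:
    """Document text plus its annotation set — the unit of validation and scoring.

    Annotation lists are kept sorted by id (numerically within the T/A/R
    prefix groups), so two documents with the same annotations compare equal
    regardless of input order.  ``extra_lines`` preserves unparsed standoff
    lines (comments, events, normalizations) verbatim.
    """

    doc_id: str
    text: str
    textbounds: list[TextBound] = field(default_factory=list)
    attributes: list[Attribute] = field(default_factory=list)
    relations: list[Relation] = field(default_factory=list)
    extra_lines: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.textbounds.sort(key=lambda t: ann_id_key(t.id))
        self.attributes.sort(key=lambda a: ann_id_key(a.id))
        self.relations.sort(key=lambda r: ann_id_key(r.id))

    # -- lookup -------------------------------------------------------------

    def textbound(self, ann_id: str) -> TextBound:
        for t in self.textbounds:
            if t.id == ann_id:
                return t
        raise KeyError(ann_id)

    @property
    def all_ids(self) -> set[str]:
        ids = {t.id for t in self.textbounds}
        ids.update(a.id for a in self.attributes)
        ids.update(r.id for r in self.relations)
        return ids

    def flags_of(self, ann_id: str) -> set[str]:
        """Names of value-less (flag) attributes attached to an annotation."""
        return {a.name for a in self.attributes if a.target == ann_id and a.value is None}

    def next_id(self, prefix: str) -> str:
        n = 0
        for ann_id in self.all_ids:
            m = _ID_RE.match(ann_id)
            if m and m.group(1) == prefix:
                n = max(n, int(m.group(2)))
        return f"{prefix}{n + 1}"

    # -- invariants ----------------------------------------------------------

    def check_invariants(self) -> None:
        """Raise :class:`DocumentInvariantError` on the first violation."""
        ids: set[str] = set()
        for ann_id in [t.id for t in self.textbounds] + [a.id for a in self.attributes] + [
            r.id for r in self.relations
        ]:
            if ann_id in ids:
                raise DocumentInvariantError(f"duplicate id {ann_id}")
            ids.add(ann_id)
        n = len(self.text)
        tb_ids = {t.id for t in self.textbounds}
        for t in self.textbounds:
            if t.span.start < 0 or t.span.end > n:
                raise DocumentInvariantError(f"{t.id}: span outside text")
            if t.surface != t.span.extract(self.text):
                raise DocumentInvariantError(f"{t.id}: surface/text mismatch")
        for a in self.attributes:
            if a.target not in ids:
                raise DocumentInvariantError(f"{a.id}: dangling target {a.target}")
        for r in self.relations:
            if r.source == r.target:
                raise DocumentInvariantError(f"{r.id}: source equals target")
            for ep in (r.source, r.target):
                if ep not in tb_ids:
                    raise DocumentInvariantError(f"{r.id}: dangling argument {ep}")

    def copy(self) -> "AnnotatedDocument":
        return AnnotatedDocument(
            doc_id=self.doc_id,
            text=self.text,
            textbounds=list(self.textbounds),
            attributes=list(self.attributes),
            relations=list(self.relations),
            extra_lines=list(self.extra_lines),
        )
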