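"""BRAT standoff reading and writing, plus annotation.conf generation.

A corpus on disk is a directory of ``<doc_id>.txt`` / ``<doc_id>.ann`` pairs.
Parsing is scheme-agnostic: every T-line becomes a :class:`TextBound`
regardless of whether its type is an entity or an anchored-attribute marker;
the distinction is drawn by the validator.  Serialization is deterministic
(ids sorted numerically within T/A/R groups) so identical documents produce
byte-identical .ann files.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable

from .annotations import (
    AnnotatedDocument,
    Attribute,
    DocumentInvariantError,
    Relation,
    TextBound,
    TextSpan,
    ann_id_key,
)
from .scheme import SchemeDefinition

__all__ = [
    "StandoffParseError",
    "parse_ann",
    "write_ann",
    "read_document",
    "write_document",
    "read_corpus",
    "write_corpus",
    "generate_brat_conf",
]

_PASSTHROUGH_PREFIXES = ("#", "E", "N", "*")


class StandoffParseError(ValueError):
    """A .ann line could not be parsed; carries the 1-based line number."""

    def __init__(self, line_no: int, message: str):
        super().__init__(f"line {line_no}: {message}")
        self.line_no = line_no


def _parse_offsets(raw: str, line_no: int) -> TextSpan:
    fragments = []
    for group in raw.split(";"):
        parts = group.split()
        if len(parts) != 2:
            raise StandoffParseError(line_no, f"bad offset group {group!r}")
        try:
            fragments.append((int(parts[0]), int(parts[1])))
        except ValueError:
            raise StandoffParseError(line_no, f"non-integer offset in {group!r}")
    try:
        return TextSpan(tuple(fragments))
    except DocumentInvariantError as exc:
        raise StandoffParseError(line_no, str(exc)) from exc


def parse_ann(ann_content: str, doc_text: str, doc_id: str = "") -> AnnotatedDocument:
    """Parse BRAT .ann content against the exact document text.

    T-lines become text-bound annotations, A-lines valued/flag attributes,
    R-lines relations (Arg1 is the source, Arg2 the target); comment, event
    and normalization lines (#, E, N, *) pass through opaquely.  Offsets
    outside the text, duplicate ids, dangling references and surface-text
    mismatches are parse errors reporting the offending line number.
    """
    textbounds: list[TextBound] = []
    attributes: list[Attribute] = []
    relations: list[Relation] = []
    extra: list[str] = []
    seen_ids: set[str] = set()

    def claim(ann_id: str, line_no: int) -> None:
        if ann_id in seen_ids:
            raise StandoffParseError(line_no, f"duplicate id {ann_id}")
        seen_ids.add(ann_id)

    for line_no, line in enumerate(ann_content.splitlines(), start=1):
        if not line.strip():
            continue
        if line[0] in _PASSTHROUGH_PREFIXES:
            extra.append(line)
            continue
        fields = line.split("\t")
        ann_id = fields[0]
        if line[0] == "T":
            if len(fields) < 3:
                raise StandoffParseError(line_no, "T-line needs 3 tab fields")
            claim(ann_id, line_no)
            type_and_offsets = fields[1]
            surface = fields[2]
            try:
                type_name, offsets = type_and_offsets.split(" ", 1)
            except ValueError:
                raise StandoffParseError(line_no, "missing offsets")
            span = _parse_offsets(offsets, line_no)
            if span.start < 0 or span.end > len(doc_text):
                raise StandoffParseError(
                    line_no, f"{ann_id}: offsets outside text (len {len(doc_text)})"
                )
            expected = span.extract(doc_text)
            # BRAT replaces newlines inside spans with spaces in the surface field
            if surface != expected and surface != expected.replace("\n", " "):
                raise StandoffParseError(
                    line_no,
                    f"{ann_id}: surface {surface!r} does not match text {expected!r}",
                )
            textbounds.append(TextBound(ann_id, type_name, span, expected))
        elif line[0] == "A" or line[0] == "M":
            if len(fields) < 2:
                raise StandoffParseError(line_no, "A-line needs 2 tab fields")
            claim(ann_id, line_no)
            parts = fields[1].split(" ")
            if len(parts) == 2:
                name, target, value = parts[0], parts[1], None
            elif len(parts) >= 3:
                name, target, value = parts[0], parts[1], " ".join(parts[2:])
            else:
                raise StandoffParseError(line_no, "A-line needs name and target")
            attributes.append(Attribute(ann_id, name, target, value))
        elif line[0] == "R":
            if len(fields) < 2:
                raise StandoffParseError(line_no, "R-line needs 2 tab fields")
            claim(ann_id, line_no)
            m = re.match(r"^(\S+) Arg1:(\S+) Arg2:(\S+)$", fields[1])
            if not m:
                raise StandoffParseError(line_no, f"bad R-line body {fields[1]!r}")
            relations.append(Relation(ann_id, m.group(1), m.group(2), m.group(3)))
        else:
            raise StandoffParseError(line_no, f"unknown line type {line[0]!r}")

    tb_ids = {t.id for t in textbounds}
    for line_no_msg, a in ((f"attribute {a.id}", a) for a in attributes):
        if a.target not in seen_ids:
            raise StandoffParseError(0, f"{line_no_msg}: dangling target {a.target}")
    for r in relations:
        for ep in (r.source, r.target):
            if ep not in tb_ids:
                raise StandoffParseError(0, f"relation {r.id}: dangling argument {ep}")

    return AnnotatedDocument(
        doc_id=doc_id,
        text=doc_text,
        textbounds=textbounds,
        attributes=attributes,
        relations=relations,
        extra_lines=extra,
    )


def write_ann(document: AnnotatedDocument) -> str:
    """Serialize a document's annotations to .ann content.

    Output is byte-stable: T-lines, then A-lines, then R-lines, each group
    sorted numerically by id, then any pass-through lines in original order.
    Documents violating structural invariants are refused.
    """
    document.check_invariants()
    lines: list[str] = []
    for t in sorted(document.textbounds, key=lambda t: ann_id_key(t.id)):
        offsets = ";".join(f"{s} {e}" for s, e in t.span.fragments)
        # BRAT writes the surface field with newlines flattened to spaces
        lines.append(f"{t.id}\t{t.type} {offsets}\t{t.surface.replace(chr(10), ' ')}")
    for a in sorted(document.attributes, key=lambda a: ann_id_key(a.id)):
        if a.value is None:
            lines.append(f"{a.id}\t{a.name} {a.target}")
        else:
            lines.append(f"{a.id}\t{a.name} {a.target} {a.value}")
    for r in sorted(document.relations, key=lambda r: ann_id_key(r.id)):
        lines.append(f"{r.id}\t{r.name} Arg1:{r.source} Arg2:{r.target}")
    lines.extend(document.extra_lines)
    return "".join(line + "\n" for line in lines)


# -- file pairs and corpora --------------------------------------------------


def read_document(txt_path: Path | str) -> AnnotatedDocument:
    """Read a ``.txt``/``.ann`` pair given the path of either file."""
    txt_path = Path(txt_path)
    base = txt_path.with_suffix("")
    text = base.with_suffix(".txt").read_text(encoding="utf-8")
    ann_file = base.with_suffix(".ann")
    ann = ann_file.read_text(encoding="utf-8") if ann_file.exists() else ""
    return parse_ann(ann, text, doc_id=base.name)


def write_document(document: AnnotatedDocument, out_dir: Path | str) -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    txt = out_dir / f"{document.doc_id}.txt"
    ann = out_dir / f"{document.doc_id}.ann"
    txt.write_text(document.text, encoding="utf-8")
    ann.write_text(write_ann(document), encoding="utf-8")
    return txt, ann


def read_corpus(corpus_dir: Path | str, on_error="raise") -> tuple[list[AnnotatedDocument], list[tuple[str, str]]]:
    """Read every .txt/.ann pair in a directory (sorted by doc id).

    Returns (documents, failures); with ``on_error="collect"`` unreadable
    pairs are reported in ``failures`` as (doc_id, message) and skipped,
    otherwise the first error propagates.
    """
    corpus_dir = Path(corpus_dir)
    docs: list[AnnotatedDocument] = []
    failures: list[tuple[str, str]] = []
    for txt in sorted(corpus_dir.glob("*.txt")):
        try:
            docs.append(read_document(txt))
        except (StandoffParseError, OSError, UnicodeDecodeError) as exc:
            if on_error == "raise":
                raise
            failures.append((txt.stem, str(exc)))
    return docs, failures


def write_corpus(documents: Iterable[AnnotatedDocument], out_dir: Path | str) -> None:
    for doc in documents:
        write_document(doc, out_dir)


# -- BRAT configuration -------------------------------------------------------


def _kind_union(scheme: SchemeDefinition, kinds: Iterable[str]) -> str:
    concrete: set[str] = set()
    for k in kinds:
        concrete.update(scheme.expand_kind(k))
    return "|".join(sorted(concrete)) if concrete else "<NONE>"


def generate_brat_conf(scheme: SchemeDefinition) -> str:
    """Emit BRAT ``annotation.conf`` content for a scheme.

    The entities section lists every entity type and every text-anchored
    attribute (markers are text-bound in BRAT); the relations section lists
    one line per relation with Arg1/Arg2 type unions; the attributes section
    lists valued attributes with their value inventories and flags as binary
    attributes.  Output ordering is alphabetical within sections, so it is
    independent of declaration order and idempotent.
    """
    lines = ["[entities]", ""]
    entity_like = [e.name for e in scheme.entity_types] + [
        a.name for a in scheme.attributes if a.anchoring == "text_anchored"
    ]
    lines.extend(sorted(entity_like))
    lines += ["", "[relations]", ""]
    for r in sorted(scheme.relations, key=lambda r: r.name):
        arg1 = _kind_union(scheme, (p[0] for p in r.allowed_pairs))
        arg2 = _kind_union(scheme, (p[1] for p in r.allowed_pairs))
        lines.append(f"{r.name}\tArg1:{arg1}, Arg2:{arg2}")
    lines += ["", "[events]", "", "", "[attributes]", ""]
    for a in sorted(scheme.attributes, key=lambda a: a.name):
        if a.anchoring != "valued":
            continue
        targets = _kind_union(scheme, a.applicable_to)
        values = "|".join(a.allowed_values)
        lines.append(f"{a.name}\tArg:{targets}, Value:{values}")
    for a in sorted(scheme.flag_attributes, key=lambda a: a.name):
        targets = _kind_union(scheme, a.applicable_to)
        lines.append(f"{a.name}\tArg:{targets}")
    return "".join(line + "\n" for line in lines)
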