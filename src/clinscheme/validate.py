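"""Constraint validation of annotated documents against a scheme.

Every violation is reported (never thrown) with a stable code from a closed
set, so corpora can be checked mechanically and violation counts compared
across runs.  Codes:

``UNKNOWN_TYPE``
    An annotation's type/name is not declared by the scheme.
``SPAN_BOUNDS``
    A text-bound annotation's span falls outside the document text.
``REL_ARGS``
    A relation's (source kind, target kind) is not an allowed argument pair;
    a text-anchored attribute marker contributes its attribute name as kind.
``ATTR_TARGET``
    A valued attribute is attached to an annotation it does not apply to
    (e.g. DocTime on a non-event entity).
``VALUE_DOMAIN``
    A valued attribute's value is outside its closed value list (or a flag
    carries a value / a valued attribute carries none).
``FLAG_SCOPE``
    A flag is attached outside its scope (e.g. a coreferent-pronoun flag on
    a non-Persons mention).
``ANCHORING``
    An annotation is realized with the wrong anchoring (e.g. a valued
    attribute name used as a text-bound type).
``ANCHOR_LINKED`` (warning severity)
    A text-anchored attribute marker participates in no relation of its
    linking family.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .annotations import AnnotatedDocument, ann_id_key
from .scheme import SchemeDefinition, UnknownNameError

__all__ = [
    "ISSUE_CODES",
    "ValidationIssue",
    "ValidationReport",
    "CorpusValidation",
    "validate_document",
    "validate_corpus",
]

ISSUE_CODES = (
    "UNKNOWN_TYPE",
    "SPAN_BOUNDS",
    "REL_ARGS",
    "ATTR_TARGET",
    "VALUE_DOMAIN",
    "FLAG_SCOPE",
    "ANCHORING",
    "ANCHOR_LINKED",
)

#: Codes that do not make a document invalid on their own would go here;
#: ANCHOR_LINKED is advisory because the scheme links markers by convention,
#: not by a hard rule.
WARNING_CODES = frozenset({"ANCHOR_LINKED"})


@dataclass(frozen=True)
class ValidationIssue:
    code: str
    ids: tuple[str, ...]
    message: str

    @property
    def severity(self) -> str:
        return "warning" if self.code in WARNING_CODES else "error"


@dataclass
class ValidationReport:
    doc_id: str
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not self.issues

    @property
    def error_issues(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    def counts_by_code(self) -> Counter:
        return Counter(i.code for i in self.issues)


@dataclass
class CorpusValidation:
    reports: list[ValidationReport]
    failures: list[tuple[str, str]] = field(default_factory=list)

    @property
    def issue_counts(self) -> Counter:
        total: Counter = Counter()
        for r in self.reports:
            total.update(r.counts_by_code())
        return total

    @property
    def n_issues(self) -> int:
        return sum(len(r.issues) for r in self.reports)


def _kind_of(scheme: SchemeDefinition, type_name: str) -> str | None:
    """Canonical kind of a text-bound type: entity type or anchored attribute."""
    try:
        canon = scheme.canonical_kind(type_name)
    except UnknownNameError:
        return None
    if scheme.is_entity_type(canon) or scheme.is_anchored_attribute(canon):
        return canon
    return None


def validate_document(
    scheme: SchemeDefinition, document: AnnotatedDocument
) -> ValidationReport:
    """Check one document against the scheme, reporting every violation.

    Pure and deterministic: issues are ordered by (annotation id, code).
    """
    issues: list[ValidationIssue] = []

    def add(code: str, ids: Sequence[str], message: str) -> None:
        issues.append(ValidationIssue(code, tuple(ids), message))

    tb_by_id = {t.id: t for t in document.textbounds}
    n = len(document.text)

    for t in document.textbounds:
        kind = _kind_of(scheme, t.type)
        if kind is None:
            try:
                attr = scheme.attribute(t.type)
            except UnknownNameError:
                attr = None
            if attr is not None:
                add("ANCHORING", [t.id],
                    f"{t.type} is a {attr.anchoring} attribute, not text-bound")
            else:
                add("UNKNOWN_TYPE", [t.id], f"unknown text-bound type {t.type!r}")
            continue
        if t.span.start < 0 or t.span.end > n:
            add("SPAN_BOUNDS", [t.id],
                f"span ({t.span.start}, {t.span.end}) outside text of length {n}")
        if scheme.is_anchored_attribute(kind):
            linking = scheme.linking_relations(kind)
            linked = any(
                r.name in linking and t.id in (r.source, r.target)
                for r in document.relations
            )
            if linking and not linked:
                add("ANCHOR_LINKED", [t.id],
                    f"{kind} marker {t.id} participates in no linking relation")

    for a in document.attributes:
        try:
            attr = scheme.attribute(a.name)
        except UnknownNameError:
            add("UNKNOWN_TYPE", [a.id], f"unknown attribute {a.name!r}")
            continue
        if attr.anchoring == "text_anchored":
            add("ANCHORING", [a.id],
                f"{a.name} is text-anchored and cannot be an A-line")
            continue
        target_tb = tb_by_id.get(a.target)
        target_kind = _kind_of(scheme, target_tb.type) if target_tb else None
        if attr.anchoring == "valued":
            if a.value is None:
                add("VALUE_DOMAIN", [a.id], f"{a.name} requires a value")
            elif a.value not in attr.allowed_values:
                add("VALUE_DOMAIN", [a.id],
                    f"{a.name} value {a.value!r} not in {attr.allowed_values}")
            if target_kind is not None and not scheme.attribute_applicable(
                a.name, target_kind
            ):
                add("ATTR_TARGET", [a.id, a.target],
                    f"{a.name} does not apply to {target_kind}")
        else:  # flag
            if a.value is not None:
                add("VALUE_DOMAIN", [a.id], f"flag {a.name} cannot carry a value")
            if target_kind is not None and not scheme.attribute_applicable(
                a.name, target_kind
            ):
                add("FLAG_SCOPE", [a.id, a.target],
                    f"flag {a.name} does not apply to {target_kind}")

    for r in document.relations:
        try:
            scheme.relation(r.name)
        except UnknownNameError:
            add("UNKNOWN_TYPE", [r.id], f"unknown relation {r.name!r}")
            continue
        src_tb = tb_by_id.get(r.source)
        tgt_tb = tb_by_id.get(r.target)
        if src_tb is None or tgt_tb is None:
            add("REL_ARGS", [r.id], f"{r.name}: missing argument annotation")
            continue
        src_kind = _kind_of(scheme, src_tb.type)
        tgt_kind = _kind_of(scheme, tgt_tb.type)
        if src_kind is None or tgt_kind is None:
            # the unknown endpoint type is already reported on its own id
            continue
        if not scheme.relation_arguments_allowed(r.name, src_kind, tgt_kind):
            add("REL_ARGS", [r.id, r.source, r.target],
                f"{r.name} does not admit ({src_kind} -> {tgt_kind})")

    issues.sort(key=lambda i: (ann_id_key(i.ids[0]) if i.ids else ("", -1), i.code))
    return ValidationReport(doc_id=document.doc_id, issues=issues)


def validate_corpus(
    scheme: SchemeDefinition,
    documents: Iterable[AnnotatedDocument],
    failures: Iterable[tuple[str, str]] = (),
) -> CorpusValidation:
    """Validate every document; the summary pools per-document issue counts.

    ``failures`` carries (doc_id, message) pairs for pairs that could not be
    read, so corpus-level processing continues past broken files.
    """
    reports = [validate_document(scheme, d) for d in documents]
    return CorpusValidation(reports=reports, failures=list(failures))
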