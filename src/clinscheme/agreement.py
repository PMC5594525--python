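"""Agreement scoring between two annotation sets over the same text.

Implements the precision/recall/F-measure comparison used to assess
annotation quality: text-bound annotations are matched one-to-one (strict
span identity or character overlap), relations count as matched when their
name and both matched endpoints agree, and valued attributes when their
(name, value) and matched target agree.  Results are reported per type and
as micro (pooled counts) and macro (mean over types) aggregates.

F-measure between annotators is the implemented statistic; chance-corrected
coefficients are out of scope.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .annotations import AnnotatedDocument, TextBound, ann_id_key

__all__ = [
    "MatchConfig",
    "TypeScore",
    "BlockScore",
    "AgreementResult",
    "match_textbounds",
    "score",
    "pairwise_corpus_agreement",
]

SPAN_MODES = ("strict", "overlap")


@dataclass(frozen=True)
class MatchConfig:
    """Matching policy: span mode and whether types must agree.

    ``strict`` requires identical fragment lists; ``overlap`` requires at
    least one shared character (over the union of fragments for
    discontinuous spans).
    """

    span_mode: str = "strict"
    require_type: bool = True

    def __post_init__(self) -> None:
        if self.span_mode not in SPAN_MODES:
            raise ValueError(f"span_mode must be one of {SPAN_MODES}")


@dataclass(frozen=True)
class TypeScore:
    n_reference: int
    n_candidate: int
    n_matched: int

    @property
    def precision(self) -> float | None:
        if self.n_reference == 0 and self.n_candidate == 0:
            return None
        return self.n_matched / self.n_candidate if self.n_candidate else 0.0

    @property
    def recall(self) -> float | None:
        if self.n_reference == 0 and self.n_candidate == 0:
            return None
        return self.n_matched / self.n_reference if self.n_reference else 0.0

    @property
    def f1(self) -> float | None:
        p, r = self.precision, self.recall
        if p is None or r is None:
            return None
        return 2 * p * r / (p + r) if p + r > 0 else 0.0


@dataclass
class BlockScore:
    """Scores for one annotation layer (entities, relations or attributes)."""

    per_type: dict[str, TypeScore] = field(default_factory=dict)

    @property
    def micro(self) -> TypeScore:
        return TypeScore(
            n_reference=sum(t.n_reference for t in self.per_type.values()),
            n_candidate=sum(t.n_candidate for t in self.per_type.values()),
            n_matched=sum(t.n_matched for t in self.per_type.values()),
        )

    def _macro(self, attr: str) -> float | None:
        vals = [getattr(t, attr) for t in self.per_type.values()]
        vals = [v for v in vals if v is not None]
        return sum(vals) / len(vals) if vals else None

    @property
    def macro_f1(self) -> float | None:
        return self._macro("f1")

    @property
    def macro_precision(self) -> float | None:
        return self._macro("precision")

    @property
    def macro_recall(self) -> float | None:
        return self._macro("recall")

    def to_dict(self) -> dict:
        m = self.micro
        return {
            "per_type": {
                name: {
                    "n_reference": t.n_reference,
                    "n_candidate": t.n_candidate,
                    "n_matched": t.n_matched,
                    "precision": t.precision,
                    "recall": t.recall,
                    "f1": t.f1,
                }
                for name, t in sorted(self.per_type.items())
            },
            "micro": {
                "n_reference": m.n_reference,
                "n_candidate": m.n_candidate,
                "n_matched": m.n_matched,
                "precision": m.precision,
                "recall": m.recall,
                "f1": m.f1,
            },
            "macro": {
                "precision": self.macro_precision,
                "recall": self.macro_recall,
                "f1": self.macro_f1,
            },
        }


@dataclass
class AgreementResult:
    """Per-type and aggregate P/R/F for entities, relations and attributes."""

    entities: BlockScore
    relations: BlockScore
    attributes: BlockScore
    skipped_docs: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {
            "entities": self.entities.to_dict(),
            "relations": self.relations.to_dict(),
            "attributes": self.attributes.to_dict(),
        }
        if self.skipped_docs:
            out["skipped_docs"] = self.skipped_docs
        return out


# -- matching -----------------------------------------------------------------


def _overlap_length(a: TextBound, b: TextBound) -> int:
    return len(a.span.covered_characters() & b.span.covered_characters())


def match_textbounds(
    reference: AnnotatedDocument,
    candidate: AnnotatedDocument,
    config: MatchConfig = MatchConfig(),
) -> list[tuple[str, str]]:
    """One-to-one matching of text-bound annotations between two documents.

    Strict mode pairs annotations with identical fragment lists (and type,
    unless ``require_type`` is off).  Overlap mode pairs annotations sharing
    at least one character, resolved greedily by maximal overlap length with
    ties broken by smaller reference start offset; the result is
    deterministic.  Documents over different texts are refused.
    """
    if reference.text != candidate.text:
        raise ValueError("documents do not share the same underlying text")

    matches: list[tuple[str, str]] = []
    if config.span_mode == "strict":
        def key(t: TextBound):
            return (t.span.fragments, t.type) if config.require_type else t.span.fragments

        cand_pool: dict = defaultdict(list)
        for t in sorted(candidate.textbounds, key=lambda t: ann_id_key(t.id)):
            cand_pool[key(t)].append(t.id)
        for t in sorted(reference.textbounds, key=lambda t: ann_id_key(t.id)):
            pool = cand_pool.get(key(t))
            if pool:
                matches.append((t.id, pool.pop(0)))
    else:
        pairs = []
        for rt in reference.textbounds:
            for ct in candidate.textbounds:
                if config.require_type and rt.type != ct.type:
                    continue
                ovl = _overlap_length(rt, ct)
                if ovl > 0:
                    pairs.append((-ovl, rt.span.start, ct.span.start,
                                  ann_id_key(rt.id), ann_id_key(ct.id), rt.id, ct.id))
        pairs.sort()
        used_ref: set[str] = set()
        used_cand: set[str] = set()
        for *_, rid, cid in pairs:
            if rid not in used_ref and cid not in used_cand:
                matches.append((rid, cid))
                used_ref.add(rid)
                used_cand.add(cid)
    return matches


# -- scoring ------------------------------------------------------------------


def _count_block(ref_items: Mapping, cand_items: Mapping) -> BlockScore:
    """Pool keyed multisets: items agree when their (type, signature) agree."""
    block = BlockScore()
    types = set(t for t, _ in ref_items) | set(t for t, _ in cand_items)
    ref_counter = Counter(ref_items)
    cand_counter = Counter(cand_items)
    for tname in types:
        n_ref = sum(c for (t, _), c in ref_counter.items() if t == tname)
        n_cand = sum(c for (t, _), c in cand_counter.items() if t == tname)
        matched = sum(
            min(c, cand_counter[key])
            for key, c in ref_counter.items()
            if key[0] == tname
        )
        block.per_type[tname] = TypeScore(n_ref, n_cand, matched)
    return block


def score(
    matching: Sequence[tuple[str, str]],
    reference: AnnotatedDocument,
    candidate: AnnotatedDocument,
) -> AgreementResult:
    """Turn a text-bound matching into per-type precision/recall/F.

    Precision is matched/|candidate| and recall matched/|reference| per type.
    A relation is matched iff both documents assert the same relation name
    over matched endpoints; a valued attribute iff its target is matched and
    (name, value) agree.  When a type occurs in neither document its scores
    are reported as undefined (None) and skipped by the aggregates.
    """
    ref_tb = {t.id: t for t in reference.textbounds}
    cand_tb = {t.id: t for t in candidate.textbounds}
    fwd = dict(matching)

    entities = BlockScore()
    types = {t.type for t in reference.textbounds} | {t.type for t in candidate.textbounds}
    for tname in types:
        n_ref = sum(1 for t in reference.textbounds if t.type == tname)
        n_cand = sum(1 for t in candidate.textbounds if t.type == tname)
        matched = sum(1 for rid, cid in matching if ref_tb[rid].type == tname)
        entities.per_type[tname] = TypeScore(n_ref, n_cand, matched)

    # relations: signature uses matched-endpoint identity (reference ids)
    inv = {cid: rid for rid, cid in matching}
    ref_rel = Counter(
        (r.name, (r.source, r.target)) for r in reference.relations
    )
    cand_rel = Counter(
        (r.name, (inv.get(r.source), inv.get(r.target)))
        for r in candidate.relations
    )
    relations = _count_block(ref_rel, cand_rel)

    ref_attr = Counter(
        (a.name, (a.target, a.value)) for a in reference.attributes
    )
    cand_attr = Counter(
        (a.name, (inv.get(a.target), a.value)) for a in candidate.attributes
    )
    attributes = _count_block(ref_attr, cand_attr)

    return AgreementResult(entities=entities, relations=relations, attributes=attributes)


def compare_documents(
    reference: AnnotatedDocument,
    candidate: AnnotatedDocument,
    config: MatchConfig = MatchConfig(),
) -> AgreementResult:
    """Match then score two documents over the same text."""
    return score(match_textbounds(reference, candidate, config), reference, candidate)


def pairwise_corpus_agreement(
    reference_docs: Iterable[AnnotatedDocument],
    candidate_docs: Iterable[AnnotatedDocument],
    config: MatchConfig = MatchConfig(),
) -> AgreementResult:
    """Micro-pooled agreement across documents paired by doc_id.

    Documents without a counterpart are reported in ``skipped_docs`` and
    skipped.  Pooling sums per-type counts over documents, so corpus
    precision/recall are computed from pooled counts (micro).  By
    construction, swapping the two corpora swaps precision and recall.
    """
    ref_by_id = {d.doc_id: d for d in reference_docs}
    cand_by_id = {d.doc_id: d for d in candidate_docs}
    skipped = sorted(set(ref_by_id) ^ set(cand_by_id))

    pooled: dict[str, dict[str, list[int]]] = {
        "entities": defaultdict(lambda: [0, 0, 0]),
        "relations": defaultdict(lambda: [0, 0, 0]),
        "attributes": defaultdict(lambda: [0, 0, 0]),
    }
    for doc_id in sorted(set(ref_by_id) & set(cand_by_id)):
        res = compare_documents(ref_by_id[doc_id], cand_by_id[doc_id], config)
        for block_name in ("entities", "relations", "attributes"):
            block: BlockScore = getattr(res, block_name)
            for tname, ts in block.per_type.items():
                acc = pooled[block_name][tname]
                acc[0] += ts.n_reference
                acc[1] += ts.n_candidate
                acc[2] += ts.n_matched

    def build(name: str) -> BlockScore:
        b = BlockScore()
        for tname, (nr, nc, nm) in pooled[name].items():
            b.per_type[tname] = TypeScore(nr, nc, nm)
        return b

    return AgreementResult(
        entities=build("entities"),
        relations=build("relations"),
        attributes=build("attributes"),
        skipped_docs=skipped,
    )
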