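"""Synthetic scheme-conformant corpora, perturbations and labeled violations.

This module is the package's test bed: it produces small pseudo-clinical
documents whose annotation sets are correct by construction (every relation
instance drawn from the scheme's allowed pairs, every value from its closed
value list, every marker linked), controlled perturbations that simulate a
second annotator (deletions, type swaps, span shifts, with exact applied
counts), and documents carrying a known number of labeled constraint
violations for exercising the validator.

Generation is deterministic: one RNG stream per document, derived from
(seed, document index), so the same seed and config reproduce the corpus
byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from . import lexicons as lex
from .annotations import (
    AnnotatedDocument,
    Attribute,
    Relation,
    TextBound,
    TextSpan,
)
from .scheme import SchemeDefinition
from .validate import validate_document

__all__ = [
    "SynthConfig",
    "PerturbationConfig",
    "PerturbationRecord",
    "ConfigError",
    "InjectionError",
    "generate_corpus",
    "perturb",
    "inject_violations",
]


#: Violation codes whose injected documents still serialize to valid
#: standoff files (a span outside the text cannot be written or re-parsed,
#: so SPAN_BOUNDS injections exist only in memory).
SERIALIZABLE_VIOLATION_CODES = (
    "REL_ARGS",
    "VALUE_DOMAIN",
    "ATTR_TARGET",
    "UNKNOWN_TYPE",
    "FLAG_SCOPE",
)


class ConfigError(ValueError):
    """A generator configuration is unusable."""


class InjectionError(ValueError):
    """The requested number of independent violations cannot be placed."""

    def __init__(self, requested: int, achievable: int):
        super().__init__(
            f"cannot place {requested} independent violations "
            f"(achievable maximum: {achievable})"
        )
        self.achievable = achievable


@dataclass
class SynthConfig:
    """Generator knobs.

    ``relation_density`` is the probability that each optional relation a
    sentence template can assert is emitted; ``attribute_density`` plays the
    same role for valued attributes, flags, and anchored-marker/link bundles
    (a marker is never emitted without its linking relation, so generated
    documents validate clean).  ``entity_type_weights`` biases which
    sentence templates are drawn via the template's focus entity type.
    """

    seed: int = 0
    n_docs: int = 20
    mean_entities_per_doc: float = 8.0
    entity_type_weights: dict[str, float] | None = None
    relation_density: float = 0.9
    attribute_density: float = 0.9
    lexicons: dict[str, list[str]] = field(
        default_factory=lambda: dict(lex.DEFAULT_LEXICONS)
    )

    def __post_init__(self) -> None:
        for name, d in (
            ("relation_density", self.relation_density),
            ("attribute_density", self.attribute_density),
        ):
            if not 0.0 <= d <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {d}")
        if self.entity_type_weights is not None:
            ws = list(self.entity_type_weights.values())
            if any(w < 0 for w in ws):
                raise ConfigError("entity_type_weights must be nonnegative")
            if ws and not any(w > 0 for w in ws):
                raise ConfigError("entity_type_weights must not be all zero")
        if self.n_docs < 0:
            raise ConfigError("n_docs must be nonnegative")
        if self.mean_entities_per_doc <= 0:
            raise ConfigError("mean_entities_per_doc must be positive")


# -- document builder ---------------------------------------------------------


class _DocBuilder:
    """Accumulates text and annotations with exact character offsets."""

    def __init__(self, doc_id: str):
        self.doc_id = doc_id
        self._chunks: list[str] = []
        self._len = 0
        self._sentence_open = False
        self.textbounds: list[TextBound] = []
        self.attributes: list[Attribute] = []
        self.relations: list[Relation] = []

    def _append(self, s: str) -> None:
        self._chunks.append(s)
        self._len += len(s)

    def word(self, token: str) -> tuple[int, int]:
        """Append one token (space-separated within a sentence)."""
        if self._sentence_open:
            self._append(" ")
        elif self._len:
            self._append("\n")
        self._sentence_open = True
        start = self._len
        self._append(token)
        return start, self._len

    def end_sentence(self) -> None:
        self._append(".")
        self._sentence_open = False

    def tb(self, type_name: str, token: str) -> str:
        start, end = self.word(token)
        return self.tb_from_fragments(type_name, [(start, end)])

    def tb_from_fragments(
        self, type_name: str, fragments: Sequence[tuple[int, int]]
    ) -> str:
        tid = f"T{len(self.textbounds) + 1}"
        span = TextSpan(tuple(fragments))
        text = "".join(self._chunks)
        self.textbounds.append(TextBound(tid, type_name, span, span.extract(text)))
        return tid

    def attr(self, name: str, target: str, value: str | None = None) -> str:
        aid = f"A{len(self.attributes) + 1}"
        self.attributes.append(Attribute(aid, name, target, value))
        return aid

    def rel(self, name: str, source: str, target: str) -> str:
        rid = f"R{len(self.relations) + 1}"
        self.relations.append(Relation(rid, name, source, target))
        return rid

    def build(self) -> AnnotatedDocument:
        if self._sentence_open:
            self.end_sentence()
        return AnnotatedDocument(
            doc_id=self.doc_id,
            text="".join(self._chunks) + "\n",
            textbounds=self.textbounds,
            attributes=self.attributes,
            relations=self.relations,
        )


# -- generation ---------------------------------------------------------------


def _pick(rng: np.random.Generator, items: Sequence):
    return items[int(rng.integers(len(items)))]


class _Generator:
    def __init__(self, scheme: SchemeDefinition, config: SynthConfig):
        self.scheme = scheme
        self.cfg = config
        self.templates: list[tuple[str, Callable]] = [
            ("Chemicals_Drugs", self._t_medication),
            ("Chemicals_Drugs", self._t_aspect),
            ("Chemicals_Drugs", self._t_treats),
            ("Chemicals_Drugs", self._t_interacts),
            ("SignOrSymptom", self._t_symptom_assertion),
            ("SignOrSymptom", self._t_localization),
            ("MedicalProcedure", self._t_exam_reveals),
            ("MedicalProcedure", self._t_procedure_time),
            ("Disorder", self._t_measurement),
            ("LivingBeings", self._t_organism),
            ("BiologicalProcessOrFunction", self._t_biological),
            ("Devices", self._t_device),
            ("Hospital", self._t_hospital),
            ("Persons", self._t_person_performs),
            ("Genes_Proteins", self._t_gene),
            ("Concept_Idea", self._t_concept),
            ("Anatomy", self._t_anatomy_site),
        ]
        weights = config.entity_type_weights or {}
        raw = np.array(
            [float(weights.get(focus, 1.0)) for focus, _ in self.templates]
        )
        if raw.sum() <= 0:
            raise ConfigError("all sentence templates have zero weight")
        self.template_p = raw / raw.sum()
        for focus, w in zip((f for f, _ in self.templates), raw):
            if w > 0 and not config.lexicons.get(focus):
                raise ConfigError(f"empty lexicon for weighted type {focus}")

    # -- helpers ------------------------------------------------------------

    def _word_from(self, rng, type_name: str) -> str:
        return _pick(rng, self.cfg.lexicons[type_name])

    def _p_rel(self, rng) -> bool:
        return rng.random() < self.cfg.relation_density

    def _p_attr(self, rng) -> bool:
        return rng.random() < self.cfg.attribute_density

    def _maybe_doctime(self, rng, b: _DocBuilder, tid: str) -> None:
        if self._p_attr(rng):
            attr = self.scheme.attribute("DocTime")
            b.attr("DocTime", tid, _pick(rng, attr.allowed_values))

    def _temporal(self, rng, b: _DocBuilder, ttype: str) -> str:
        tid = b.tb("Temporal", _pick(rng, lex.TEMPORAL_LEXICONS[ttype]))
        if self._p_attr(rng):
            b.attr("TemporalType", tid, ttype)
        return tid

    # -- sentence templates --------------------------------------------------
    # Each returns the number of entity mentions it added.

    def _t_medication(self, rng, b: _DocBuilder) -> int:
        person = b.tb("Persons", self._word_from(rng, "Persons"))
        if self._p_attr(rng):
            b.attr("PersonType", person,
                   _pick(rng, self.scheme.attribute("PersonType").allowed_values))
        b.word("prend")
        drug = b.tb("Chemicals_Drugs", self._word_from(rng, "Chemicals_Drugs"))
        self._maybe_doctime(rng, b, drug)
        if self._p_rel(rng):
            b.rel("Experiences", person, drug)
        for attr_name in ("Strength", "AdministrationRoute", "Dosage", "DrugForm"):
            if rng.random() < self.cfg.attribute_density * 0.5:
                marker = b.tb(attr_name, _pick(rng, lex.DRUG_ATTRIBUTE_MARKERS[attr_name]))
                b.rel(f"Has{attr_name}" if attr_name != "AdministrationRoute"
                      else "HasAdministrationRoute", drug, marker)
        freq = self._temporal(rng, b, "Frequency")
        if self._p_rel(rng):
            b.rel("During", drug, freq)
        return 3

    def _t_aspect(self, rng, b: _DocBuilder) -> int:
        n = 2
        if self._p_attr(rng):
            marker_text, rel_name = lex.ASPECT_MARKERS[int(rng.integers(len(lex.ASPECT_MARKERS)))]
            marker = b.tb("Aspect", marker_text)
            drug = b.tb("Chemicals_Drugs", self._word_from(rng, "Chemicals_Drugs"))
            b.rel(rel_name, marker, drug)
        else:
            drug = b.tb("Chemicals_Drugs", self._word_from(rng, "Chemicals_Drugs"))
        self._maybe_doctime(rng, b, drug)
        b.word("le")
        date = self._temporal(rng, b, "Date")
        if self._p_rel(rng):
            b.rel("Begins_on", drug, date)
        return n

    def _t_treats(self, rng, b: _DocBuilder) -> int:
        drug = b.tb("Chemicals_Drugs", self._word_from(rng, "Chemicals_Drugs"))
        b.word("pour")
        dis = b.tb("Disorder", self._word_from(rng, "Disorder"))
        self._maybe_doctime(rng, b, dis)
        if self._p_rel(rng):
            b.rel("Treats", drug, dis)
        return 2

    def _t_interacts(self, rng, b: _DocBuilder) -> int:
        d1 = b.tb("Chemicals_Drugs", self._word_from(rng, "Chemicals_Drugs"))
        b.word("associé à")
        d2 = b.tb("Chemicals_Drugs", self._word_from(rng, "Chemicals_Drugs"))
        if self._p_rel(rng):
            b.rel("Interacts_with", d1, d2)
        return 2

    def _t_symptom_assertion(self, rng, b: _DocBuilder) -> int:
        marker = None
        if self._p_attr(rng):
            marker_text, rel_name = lex.ASSERTION_MARKERS[
                int(rng.integers(len(lex.ASSERTION_MARKERS)))
            ]
            marker = b.tb("Assertion", marker_text)
        if rng.random() < 0.3:
            # discontinuous second mention: "douleur abdominale et lombaire"
            s1 = b.word("douleur")
            s2 = b.word("abdominale")
            sos = b.tb_from_fragments("SignOrSymptom", [(s1[0], s2[1])])
            b.word("et")
            s3 = b.word("lombaire")
            sos2 = b.tb_from_fragments("SignOrSymptom", [s1, s3])
            self._maybe_doctime(rng, b, sos2)
            n = 2
        else:
            sos = b.tb("SignOrSymptom", self._word_from(rng, "SignOrSymptom"))
            n = 1
        self._maybe_doctime(rng, b, sos)
        if marker is not None:
            b.rel(rel_name, marker, sos)
        return n

    def _t_localization(self, rng, b: _DocBuilder) -> int:
        sos = b.tb("SignOrSymptom", self._word_from(rng, "SignOrSymptom"))
        self._maybe_doctime(rng, b, sos)
        if self._p_attr(rng):
            loc = b.tb("Localization", _pick(rng, lex.LOCALIZATION_MARKERS))
            b.rel("Localization_of", loc, sos)
        return 1

    def _t_exam_reveals(self, rng, b: _DocBuilder) -> int:
        proc = b.tb("MedicalProcedure", self._word_from(rng, "MedicalProcedure"))
        self._maybe_doctime(rng, b, proc)
        b.word("révèle")
        dis = b.tb("Disorder", self._word_from(rng, "Disorder"))
        b.word("du")
        ana = b.tb("Anatomy", self._word_from(rng, "Anatomy"))
        if self._p_rel(rng):
            b.rel("Reveals", proc, dis)
        if self._p_rel(rng):
            b.rel("Location_of", ana, dis)
        return 3

    def _t_procedure_time(self, rng, b: _DocBuilder) -> int:
        proc = b.tb("MedicalProcedure", self._word_from(rng, "MedicalProcedure"))
        self._maybe_doctime(rng, b, proc)
        ttype = _pick(rng, ["Duration", "Time", "Date"])
        t = self._temporal(rng, b, ttype)
        if self._p_rel(rng):
            rel_name = _pick(rng, ["Before", "During", "Ends_on", "Overlap", "Simultaneous"])
            b.rel(rel_name, proc, t)
        return 2

    def _t_measurement(self, rng, b: _DocBuilder) -> int:
        dis = b.tb("Disorder", self._word_from(rng, "Disorder"))
        self._maybe_doctime(rng, b, dis)
        if self._p_attr(rng):
            b.word("de")
            m_text, _subtype = lex.MEASUREMENT_MARKERS[
                int(rng.integers(len(lex.MEASUREMENT_MARKERS)))
            ]
            m = b.tb("Measurement", m_text)
            b.rel("Measure_of", m, dis)
        return 1

    def _t_organism(self, rng, b: _DocBuilder) -> int:
        dis = b.tb("Disorder", self._word_from(rng, "Disorder"))
        b.word("à")
        org = b.tb("LivingBeings", self._word_from(rng, "LivingBeings"))
        if self._p_rel(rng):
            b.rel("Causes", org, dis)
        return 2

    def _t_biological(self, rng, b: _DocBuilder) -> int:
        dis = b.tb("Disorder", self._word_from(rng, "Disorder"))
        b.word("du")
        bpf = b.tb("BiologicalProcessOrFunction",
                   self._word_from(rng, "BiologicalProcessOrFunction"))
        if self._p_rel(rng):
            b.rel("Affects", dis, bpf)
        return 2

    def _t_device(self, rng, b: _DocBuilder) -> int:
        dev = b.tb("Devices", self._word_from(rng, "Devices"))
        b.word("pour")
        dis = b.tb("Disorder", self._word_from(rng, "Disorder"))
        if self._p_rel(rng):
            b.rel("Treats", dev, dis)
        return 2

    def _t_hospital(self, rng, b: _DocBuilder) -> int:
        proc = b.tb("MedicalProcedure", self._word_from(rng, "MedicalProcedure"))
        b.word("réalisée à")
        hosp = b.tb("Hospital", self._word_from(rng, "Hospital"))
        if self._p_rel(rng):
            b.rel("Location_of", hosp, proc)
        return 2

    def _t_person_performs(self, rng, b: _DocBuilder) -> int:
        if self._p_attr(rng):
            person = b.tb("Persons", _pick(rng, lex.PRONOUNS))
            b.attr("CoreferentPronoun", person)
        else:
            person = b.tb("Persons", self._word_from(rng, "Persons"))
        if self._p_attr(rng):
            b.attr("PersonType", person, "HealthProfessional")
        b.word("prescrit")
        proc = b.tb("MedicalProcedure", self._word_from(rng, "MedicalProcedure"))
        if self._p_rel(rng):
            b.rel("Performs", person, proc)
        return 2

    def _t_gene(self, rng, b: _DocBuilder) -> int:
        b.word("dosage de")
        if self._p_attr(rng) and rng.random() < 0.5:
            gp = b.tb("Genes_Proteins", _pick(rng, lex.ABBREVIATION_LEXICONS["Genes_Proteins"]))
            b.attr("Abbreviation", gp)
        else:
            gp = b.tb("Genes_Proteins", self._word_from(rng, "Genes_Proteins"))
        return 1

    def _t_concept(self, rng, b: _DocBuilder) -> int:
        ci = b.tb("Concept_Idea", self._word_from(rng, "Concept_Idea"))
        self._maybe_doctime(rng, b, ci)
        b.word("surveillé")
        return 1

    def _t_anatomy_site(self, rng, b: _DocBuilder) -> int:
        proc = b.tb("MedicalProcedure", self._word_from(rng, "MedicalProcedure"))
        b.word("du")
        ana = b.tb("Anatomy", self._word_from(rng, "Anatomy"))
        if self._p_rel(rng):
            b.rel("Location_of", ana, proc)
        return 2

    # -- document/corpus -----------------------------------------------------

    def document(self, index: int) -> AnnotatedDocument:
        rng = np.random.default_rng([abs(int(self.cfg.seed)), index])
        b = _DocBuilder(f"doc-{index:04d}")
        target = max(1, int(rng.poisson(self.cfg.mean_entities_per_doc)))
        n = 0
        while n < target:
            idx = int(rng.choice(len(self.templates), p=self.template_p))
            n += self.templates[idx][1](rng, b)
            b.end_sentence()
        return b.build()

    def corpus(self) -> list[AnnotatedDocument]:
        return [self.document(i) for i in range(self.cfg.n_docs)]


def generate_corpus(
    scheme: SchemeDefinition, config: SynthConfig | None = None
) -> list[AnnotatedDocument]:
    """Generate a scheme-conformant synthetic corpus.

    Every produced document validates clean against the scheme; identical
    seed and config reproduce the corpus exactly.
    """
    return _Generator(scheme, config or SynthConfig()).corpus()


# -- perturbation -------------------------------------------------------------


@dataclass
class PerturbationConfig:
    """Second-annotator simulation: rates of deletion, type swap, span shift.

    Rates are per text-bound annotation; when several operations fire for
    the same annotation, deletion takes precedence over type swap over span
    shift.  Span shifts move the whole span by up to ``span_shift_max``
    characters, staying within the text.
    """

    seed: int = 0
    deletion_rate: float = 0.0
    type_swap_rate: float = 0.0
    span_shift_rate: float = 0.0
    span_shift_max: int = 2

    def __post_init__(self) -> None:
        for name in ("deletion_rate", "type_swap_rate", "span_shift_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")


@dataclass
class PerturbationRecord:
    """Exactly how many operations were applied."""

    n_textbounds: int = 0
    deleted: int = 0
    type_swapped: int = 0
    span_shifted: int = 0
    deleted_relations: int = 0
    deleted_attributes: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def perturb(
    document: AnnotatedDocument,
    config: PerturbationConfig,
    scheme: SchemeDefinition | None = None,
) -> tuple[AnnotatedDocument, PerturbationRecord]:
    """Produce a perturbed copy of a document plus exact applied counts.

    Deleting an annotation removes it together with all incident relations
    and attributes.  Type swaps pick a different entity type uniformly
    (drawn from the scheme's inventory when given, else from the types
    present in the document) and only apply to entity-typed annotations.
    """
    rng = np.random.default_rng(abs(int(config.seed)))
    rec = PerturbationRecord(n_textbounds=len(document.textbounds))

    if scheme is not None:
        entity_types = [e.name for e in scheme.entity_types]
    else:
        entity_types = sorted({t.type for t in document.textbounds})

    def is_entity(tb: TextBound) -> bool:
        if scheme is None:
            return True
        return scheme.is_entity_type(tb.type)

    kept: list[TextBound] = []
    deleted_ids: set[str] = set()
    n = len(document.text)
    for tb in document.textbounds:
        u_del = rng.random()
        u_swap = rng.random()
        u_shift = rng.random()
        if u_del < config.deletion_rate:
            deleted_ids.add(tb.id)
            rec.deleted += 1
            continue
        if u_swap < config.type_swap_rate and is_entity(tb):
            others = [t for t in entity_types if t != tb.type]
            if others:
                tb = replace(tb, type=_pick(rng, others))
                rec.type_swapped += 1
        if u_shift < config.span_shift_rate:
            k = int(rng.integers(1, config.span_shift_max + 1))
            delta = k if rng.random() < 0.5 else -k
            for d in (delta, -delta):
                moved = tb.span.shifted(d)
                if moved.start >= 0 and moved.end <= n:
                    tb = replace(
                        tb, span=moved, surface=moved.extract(document.text)
                    )
                    rec.span_shifted += 1
                    break
        kept.append(tb)

    relations = []
    for r in document.relations:
        if r.source in deleted_ids or r.target in deleted_ids:
            rec.deleted_relations += 1
        else:
            relations.append(r)
    attributes = []
    for a in document.attributes:
        if a.target in deleted_ids:
            rec.deleted_attributes += 1
        else:
            attributes.append(a)

    out = AnnotatedDocument(
        doc_id=document.doc_id,
        text=document.text,
        textbounds=kept,
        attributes=attributes,
        relations=relations,
        extra_lines=list(document.extra_lines),
    )
    return out, rec


# -- violation injection ------------------------------------------------------


def inject_violations(
    scheme: SchemeDefinition,
    document: AnnotatedDocument,
    n: int,
    seed: int = 0,
    codes: Sequence[str] | None = None,
) -> tuple[AnnotatedDocument, list[tuple[str, str]]]:
    """Inject exactly *n* independently detectable constraint violations.

    Each violation targets a distinct annotation (no masking: the validator
    finds exactly *n* issues, whose codes and primary annotation ids equal
    the returned labels).  ``codes`` optionally restricts the violation
    kinds.  Raises :class:`InjectionError` with the achievable maximum if
    *n* independent violations cannot be placed, and ValueError if the
    input document does not validate clean or ``n < 1``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base_report = validate_document(scheme, document)
    if base_report.issues:
        raise ValueError("document must validate clean before injection")

    doc = document.copy()
    tb_by_id = {t.id: t for t in doc.textbounds}
    referenced: set[str] = set()
    for r in doc.relations:
        referenced.update((r.source, r.target))
    for a in doc.attributes:
        referenced.add(a.target)

    relation_names = [r.name for r in scheme.relations]

    # Each action: (code, label_id, touched ids, apply callable)
    actions: list[tuple[str, str, frozenset[str], Callable]] = []

    for i, r in enumerate(doc.relations):
        src = tb_by_id.get(r.source)
        tgt = tb_by_id.get(r.target)
        if src is None or tgt is None:
            continue
        if not (scheme.is_entity_type(src.type) and scheme.is_entity_type(tgt.type)):
            continue
        sk, tk = scheme.canonical_kind(src.type), scheme.canonical_kind(tgt.type)
        forbidden = [
            name
            for name in relation_names
            if (sk, tk) not in scheme.allowed_pairs_expanded(name)
        ]
        if forbidden:
            def apply_rel(rng, idx=i, options=tuple(forbidden)):
                rel = doc.relations[idx]
                doc.relations[idx] = replace(rel, name=_pick(rng, options))

            actions.append(("REL_ARGS", r.id, frozenset({r.id}), apply_rel))

    entity_tbs = [t for t in doc.textbounds if scheme.is_entity_type(t.type)]
    for i, a in enumerate(doc.attributes):
        adef = scheme.attribute(a.name)
        if adef.anchoring == "valued":
            def apply_val(rng, idx=i):
                att = doc.attributes[idx]
                doc.attributes[idx] = replace(att, value="ValeurInvalide")

            actions.append(("VALUE_DOMAIN", a.id, frozenset({a.id}), apply_val))
            bad_targets = [
                t.id
                for t in entity_tbs
                if not scheme.attribute_applicable(a.name, t.type)
            ]
            for bt in bad_targets[:3]:
                def apply_retgt(rng, idx=i, new_target=bt):
                    att = doc.attributes[idx]
                    doc.attributes[idx] = replace(att, target=new_target)

                actions.append(
                    ("ATTR_TARGET", a.id, frozenset({a.id, bt}), apply_retgt)
                )

    for i, t in enumerate(doc.textbounds):
        if t.id not in referenced and scheme.is_entity_type(t.type):
            def apply_unk(rng, idx=i):
                tb = doc.textbounds[idx]
                doc.textbounds[idx] = replace(tb, type="TypeInconnu")

            actions.append(("UNKNOWN_TYPE", t.id, frozenset({t.id}), apply_unk))

        def apply_span(rng, idx=i):
            tb = doc.textbounds[idx]
            m = len(doc.text)
            doc.textbounds[idx] = replace(
                tb, span=TextSpan.single(m + 1, m + 1 + max(1, tb.span.end - tb.span.start))
            )

        actions.append(("SPAN_BOUNDS", t.id, frozenset({t.id}), apply_span))

    flag_def = None
    try:
        flag_def = scheme.attribute("CoreferentPronoun")
    except Exception:
        pass
    if flag_def is not None:
        for t in entity_tbs:
            if not scheme.attribute_applicable("CoreferentPronoun", t.type):
                def apply_flag(rng, target=t.id):
                    aid = doc.next_id("A")
                    doc.attributes.append(
                        Attribute(aid, "CoreferentPronoun", target)
                    )
                    return aid

                actions.append(
                    ("FLAG_SCOPE", "", frozenset({t.id}), apply_flag)
                )

    if codes is not None:
        allowed = set(codes)
        actions = [a for a in actions if a[0] in allowed]

    # Greedy selection of actions with pairwise-disjoint touched sets, in a
    # seed-determined order.
    rng = np.random.default_rng(abs(int(seed)))
    order = rng.permutation(len(actions))
    chosen: list[tuple[str, str, frozenset[str], Callable]] = []
    used: set[str] = set()
    for j in order:
        code, label_id, touched, fn = actions[int(j)]
        if touched & used:
            continue
        chosen.append((code, label_id, touched, fn))
        used |= touched
        if len(chosen) == n:
            break
    if len(chosen) < n:
        raise InjectionError(n, len(chosen))

    labels: list[tuple[str, str]] = []
    for code, label_id, _touched, fn in chosen:
        new_id = fn(rng)
        labels.append((code, new_id if new_id is not None else label_id))
    return doc, labels
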