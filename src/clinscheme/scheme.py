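"""Typed annotation scheme for clinical narratives.

The scheme is a closed inventory of entity types (a subset of which are
*events*), attributes (text-anchored markers, normalized-value attributes and
boolean flags) and directed binary relations grouped into five families
(event-related, aspect, assertion, drug-attribute, temporal).  Relation and
attribute applicability are closed-world: any (source kind, target kind)
combination not declared by the scheme is invalid.

The default instance shipped with the package models clinical text along the
lines of the major clinical NLP annotation efforts: entity categories derived
from UMLS Semantic Groups plus added categories (SignOrSymptom, Persons,
Hospital, Temporal), TimeML-derived temporal expressions and document-time
anchoring, and medication attributes (route, dosage, form, strength).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import yaml

__all__ = [
    "ANY_ENTITY",
    "EVENT_ENTITY",
    "EVENT_OR_TEMPORAL",
    "WILDCARD_CLASSES",
    "RELATION_FAMILIES",
    "EntityTypeDef",
    "AttributeDef",
    "RelationDef",
    "SchemeDefinition",
    "SchemeError",
    "UnknownNameError",
    "load_scheme",
    "load_default_scheme",
]

ANY_ENTITY = "ANY_ENTITY"
EVENT_ENTITY = "EVENT_ENTITY"
EVENT_OR_TEMPORAL = "EVENT_OR_TEMPORAL"
WILDCARD_CLASSES = (ANY_ENTITY, EVENT_ENTITY, EVENT_OR_TEMPORAL)

RELATION_FAMILIES = (
    "event_related",
    "aspect",
    "assertion",
    "drug_attribute",
    "temporal",
)

ANCHORINGS = ("text_anchored", "valued", "flag")
PROVENANCES = ("umls_semantic_group", "added_category")

_NAME_RE = re.compile(r"^[^\s/]+$")  # BRAT-safe: no whitespace, no "/"


class SchemeError(ValueError):
    """A scheme definition violates the scheme invariants."""


class UnknownNameError(LookupError):
    """A name does not resolve against the scheme (distinct from False)."""


@dataclass(frozen=True)
class EntityTypeDef:
    """One entity category, e.g. Disorder or Chemicals_Drugs.

    ``is_event`` marks the event subset: entity types eligible for DocTime
    attributes and temporal relations.  ``provenance`` records whether the
    category comes from a UMLS Semantic Group or was added for clinical
    interest; ``umls_semantic_types`` lists the UMLS semantic types that map
    onto the category (possibly empty, e.g. Hospital).
    """

    name: str
    aliases: tuple[str, ...] = ()
    is_event: bool = False
    provenance: str = "added_category"
    umls_semantic_types: tuple[str, ...] = ()


@dataclass(frozen=True)
class AttributeDef:
    """One attribute definition.

    ``anchoring`` distinguishes text-anchored attributes (their own markable
    span, linked to the target through a relation), valued attributes (a
    normalized value from ``allowed_values`` attached to an annotation) and
    boolean flags.  ``linking`` names the relation family, or the individual
    relation, that ties a text-anchored marker to its target.
    """

    name: str
    anchoring: str
    allowed_values: tuple[str, ...] = ()
    subtypes: tuple[str, ...] = ()
    applicable_to: tuple[str, ...] = ()
    linking: str | None = None


@dataclass(frozen=True)
class RelationDef:
    """A directed binary relation with a closed list of allowed argument pairs.

    Source/target kinds may be entity-type names, text-anchored attribute
    names, or one of the wildcard classes.  Bidirectional table rows are
    expanded to two directed pairs at load time; ``allowed_pairs`` is always
    directed.
    """

    name: str
    family: str
    allowed_pairs: tuple[tuple[str, str], ...]
    aliases: tuple[str, ...] = ()


@dataclass(frozen=True)
class SchemeSummary:
    n_entity_types: int
    n_attributes: int
    n_relations: int
    n_event_types: int
    family_counts: Mapping[str, int]


@dataclass
class SchemeDefinition:
    """The complete type system: entities, attributes, relations.

    ``semantic_type_map`` maps UMLS semantic-type names to entity-type names
    and is derived from the per-entity semantic-type lists.
    """

    entity_types: list[EntityTypeDef] = field(default_factory=list)
    attributes: list[AttributeDef] = field(default_factory=list)
    flag_attributes: list[AttributeDef] = field(default_factory=list)
    relations: list[RelationDef] = field(default_factory=list)
    semantic_type_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._check()
        self._alias_map: dict[str, str] = {}
        for e in self.entity_types:
            for a in e.aliases:
                self._alias_map[a] = e.name
        self._entities = {e.name: e for e in self.entity_types}
        self._attrs = {a.name: a for a in self.attributes + self.flag_attributes}
        self._rels: dict[str, RelationDef] = {}
        for r in self.relations:
            self._rels[r.name] = r
            for a in r.aliases:
                self._rels.setdefault(a, r)

    # -- construction-time checks ------------------------------------------

    def _check(self) -> None:
        seen: set[str] = set()
        for e in self.entity_types:
            if not _NAME_RE.match(e.name):
                raise SchemeError(f"entity type name not BRAT-safe: {e.name!r}")
            if e.name in seen:
                raise SchemeError(f"duplicate entity type: {e.name}")
            if e.provenance not in PROVENANCES:
                raise SchemeError(f"{e.name}: unknown provenance {e.provenance!r}")
            seen.add(e.name)
        for a in self.attributes + self.flag_attributes:
            if a.name in seen:
                raise SchemeError(f"attribute name collides: {a.name}")
            seen.add(a.name)
            if a.anchoring not in ANCHORINGS:
                raise SchemeError(f"{a.name}: unknown anchoring {a.anchoring!r}")
            if a.anchoring == "valued" and not a.allowed_values:
                raise SchemeError(f"{a.name}: valued attribute needs allowed_values")
            if a.anchoring in ("text_anchored", "flag") and a.allowed_values:
                raise SchemeError(f"{a.name}: {a.anchoring} attribute has values")
        for r in self.relations:
            if r.family not in RELATION_FAMILIES:
                raise SchemeError(f"{r.name}: unknown family {r.family!r}")
            if not r.allowed_pairs:
                raise SchemeError(f"{r.name}: empty allowed_pairs")
        # referential closure of kinds
        kinds = self._declared_kinds()
        for a in self.attributes + self.flag_attributes:
            for k in a.applicable_to:
                if k not in kinds:
                    raise SchemeError(f"{a.name}: unknown target kind {k!r}")
        for r in self.relations:
            for src, tgt in r.allowed_pairs:
                for k in (src, tgt):
                    if k not in kinds:
                        raise SchemeError(f"{r.name}: unknown kind {k!r}")

    def _declared_kinds(self) -> set[str]:
        kinds = {e.name for e in self.entity_types}
        kinds.update(a.name for a in self.attributes if a.anchoring == "text_anchored")
        kinds.update(WILDCARD_CLASSES)
        return kinds

    # -- name resolution ----------------------------------------------------

    def canonical_kind(self, name: str) -> str:
        """Resolve an entity/attribute kind name or alias to its canonical form."""
        if name in self._entities or name in self._attrs or name in WILDCARD_CLASSES:
            return name
        if name in self._alias_map:
            return self._alias_map[name]
        raise UnknownNameError(f"unknown kind: {name!r}")

    def entity_type(self, name: str) -> EntityTypeDef:
        try:
            return self._entities[self.canonical_kind(name)]
        except (KeyError, UnknownNameError):
            raise UnknownNameError(f"unknown entity type: {name!r}") from None

    def attribute(self, name: str) -> AttributeDef:
        try:
            return self._attrs[name]
        except KeyError:
            raise UnknownNameError(f"unknown attribute: {name!r}") from None

    def relation(self, name: str) -> RelationDef:
        try:
            return self._rels[name]
        except KeyError:
            raise UnknownNameError(f"unknown relation: {name!r}") from None

    def is_entity_type(self, name: str) -> bool:
        try:
            return self.canonical_kind(name) in self._entities
        except UnknownNameError:
            return False

    def is_anchored_attribute(self, name: str) -> bool:
        a = self._attrs.get(name)
        return a is not None and a.anchoring == "text_anchored"

    # -- wildcard expansion and constraint lookups --------------------------

    @property
    def event_types(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.entity_types if e.is_event)

    def expand_kind(self, kind: str) -> frozenset[str]:
        """Expand a wildcard class to concrete kind names (identity otherwise)."""
        if kind == ANY_ENTITY:
            return frozenset(self._entities)
        if kind == EVENT_ENTITY:
            return frozenset(self.event_types)
        if kind == EVENT_OR_TEMPORAL:
            out = set(self.event_types)
            if "Temporal" in self._entities:
                out.add("Temporal")
            return frozenset(out)
        return frozenset({self.canonical_kind(kind)})

    def allowed_pairs_expanded(self, relation: str) -> frozenset[tuple[str, str]]:
        """All concrete (source kind, target kind) pairs a relation admits."""
        r = self.relation(relation)
        out: set[tuple[str, str]] = set()
        for src, tgt in r.allowed_pairs:
            for s in self.expand_kind(src):
                for t in self.expand_kind(tgt):
                    out.add((s, t))
        return frozenset(out)

    def relation_arguments_allowed(
        self, relation: str, source_kind: str, target_kind: str
    ) -> bool:
        """True iff (source, target) is an allowed argument pair of *relation*.

        Closed world: a pair absent from the declared inventory is invalid.
        Unknown relation or kind names raise :class:`UnknownNameError`.
        """
        src = self.canonical_kind(source_kind)
        tgt = self.canonical_kind(target_kind)
        return (src, tgt) in self.allowed_pairs_expanded(relation)

    def attribute_applicable(self, attribute: str, target_kind: str) -> bool:
        """True iff *attribute* may be attached to an annotation of *target_kind*."""
        a = self.attribute(attribute)
        tgt = self.canonical_kind(target_kind)
        allowed: set[str] = set()
        for k in a.applicable_to:
            allowed.update(self.expand_kind(k))
        return tgt in allowed

    def linking_relations(self, attribute: str) -> frozenset[str]:
        """Relation names that may tie a text-anchored marker to its target."""
        a = self.attribute(attribute)
        if a.linking is None:
            return frozenset()
        if a.linking in RELATION_FAMILIES:
            return frozenset(r.name for r in self.relations if r.family == a.linking)
        return frozenset({self.relation(a.linking).name})

    def map_semantic_type(self, sty_name: str) -> str | None:
        """Entity type for a UMLS semantic-type name, or None if unmapped."""
        return self.semantic_type_map.get(sty_name)

    # -- enumeration --------------------------------------------------------

    def summary(self) -> SchemeSummary:
        """Inventory counts, computed by enumeration."""
        fam = {f: 0 for f in RELATION_FAMILIES}
        for r in self.relations:
            fam[r.family] += 1
        return SchemeSummary(
            n_entity_types=len(self.entity_types),
            n_attributes=len(self.attributes),
            n_relations=len(self.relations),
            n_event_types=sum(1 for e in self.entity_types if e.is_event),
            family_counts=fam,
        )

    def constraint_index(self) -> dict[str, tuple[str, str, str]]:
        """Stable constraint IDs, one per declared relation argument pair.

        E.g. ``REL.TREATS.1 -> ("Treats", "Chemicals_Drugs", "Disorder")``.
        """
        out: dict[str, tuple[str, str, str]] = {}
        for r in self.relations:
            for i, (src, tgt) in enumerate(r.allowed_pairs, start=1):
                out[f"REL.{r.name.upper()}.{i}"] = (r.name, src, tgt)
        return out


# -- loading ----------------------------------------------------------------


def _load_entity(raw: dict, idx: int) -> EntityTypeDef:
    try:
        return EntityTypeDef(
            name=raw["name"],
            aliases=tuple(raw.get("aliases", ())),
            is_event=bool(raw.get("is_event", False)),
            provenance=raw.get("provenance", "added_category"),
            umls_semantic_types=tuple(raw.get("umls_semantic_types", ())),
        )
    except (KeyError, TypeError) as exc:
        raise SchemeError(f"entity_types[{idx}]: {exc}") from exc


def _load_attribute(raw: dict, idx: int, section: str) -> AttributeDef:
    try:
        return AttributeDef(
            name=raw["name"],
            anchoring=raw["anchoring"],
            allowed_values=tuple(raw.get("allowed_values", ())),
            subtypes=tuple(raw.get("subtypes", ())),
            applicable_to=tuple(raw.get("applicable_to", ())),
            linking=raw.get("linking"),
        )
    except (KeyError, TypeError) as exc:
        raise SchemeError(f"{section}[{idx}]: {exc}") from exc


def _load_relation(raw: dict, idx: int) -> RelationDef:
    try:
        pairs: list[tuple[str, str]] = []
        for p in raw["allowed_pairs"]:
            if len(p) == 3 and p[2] == "bidirectional":
                pairs.append((p[0], p[1]))
                pairs.append((p[1], p[0]))
            elif len(p) == 2:
                pairs.append((p[0], p[1]))
            else:
                raise SchemeError(
                    f"relations[{idx}] ({raw.get('name')}): bad pair {p!r}"
                )
        return RelationDef(
            name=raw["name"],
            family=raw["family"],
            allowed_pairs=tuple(pairs),
            aliases=tuple(raw.get("aliases", ())),
        )
    except (KeyError, TypeError) as exc:
        raise SchemeError(f"relations[{idx}]: {exc}") from exc


def scheme_from_mapping(raw: Mapping) -> SchemeDefinition:
    """Build a SchemeDefinition from a parsed config mapping."""
    if not isinstance(raw, Mapping):
        raise SchemeError("scheme config must be a mapping")
    entities = [
        _load_entity(e, i) for i, e in enumerate(raw.get("entity_types", ()))
    ]
    attributes = [
        _load_attribute(a, i, "attributes")
        for i, a in enumerate(raw.get("attributes", ()))
    ]
    flags = [
        _load_attribute(a, i, "flag_attributes")
        for i, a in enumerate(raw.get("flag_attributes", ()))
    ]
    relations = [
        _load_relation(r, i) for i, r in enumerate(raw.get("relations", ()))
    ]
    sty_map: dict[str, str] = {}
    for e in entities:
        for sty in e.umls_semantic_types:
            sty_map[sty] = e.name
    return SchemeDefinition(
        entity_types=entities,
        attributes=attributes,
        flag_attributes=flags,
        relations=relations,
        semantic_type_map=sty_map,
    )


def load_scheme(path) -> SchemeDefinition:
    """Load a scheme definition from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return scheme_from_mapping(raw)


def load_default_scheme() -> SchemeDefinition:
    """Load the scheme instance shipped with the package.

    The default scheme has 13 entity types (6 of them events), 11 attributes
    plus 2 flags, and 37 relations (15 event-related, 8 aspect, 4 assertion,
    4 drug-attribute, 6 temporal).
    """
    ref = resources.files("clinscheme").joinpath("data/default_scheme.yaml")
    raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return scheme_from_mapping(raw)
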