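"""The scheme type system and its shipped default instance."""

import pytest

from clinscheme import (
    SchemeDefinition,
    SchemeError,
    UnknownNameError,
    load_default_scheme,
)
from clinscheme.scheme import scheme_from_mapping

EVENT_TYPES = {
    "Disorder",
    "SignOrSymptom",
    "MedicalProcedure",
    "Chemicals_Drugs",
    "BiologicalProcessOrFunction",
    "Concept_Idea",
}


class TestDefaultInventory:
    def test_counts(self, scheme):
        s = scheme.summary()
        assert s.n_entity_types == 13
        assert s.n_attributes == 11
        assert s.n_relations == 37
        assert s.n_event_types == 6

    def test_relation_family_partition(self, scheme):
        fam = scheme.summary().family_counts
        assert fam == {
            "event_related": 15,
            "aspect": 8,
            "assertion": 4,
            "drug_attribute": 4,
            "temporal": 6,
        }
        assert sum(fam.values()) == scheme.summary().n_relations

    def test_event_subset(self, scheme):
        assert set(scheme.event_types) == EVENT_TYPES
        assert scheme.entity_type("Temporal").is_event is False

    def test_provenance_split(self, scheme):
        by_prov = {"umls_semantic_group": 0, "added_category": 0}
        for e in scheme.entity_types:
            by_prov[e.provenance] += 1
        assert by_prov == {"umls_semantic_group": 9, "added_category": 4}

    def test_temporal_relation_family_members(self, scheme):
        temporal = {r.name for r in scheme.relations if r.family == "temporal"}
        assert temporal == {
            "Before", "Begins_on", "During", "Ends_on", "Overlap", "Simultaneous"
        }

    def test_temporal_type_and_doctime_values(self, scheme):
        assert set(scheme.attribute("TemporalType").allowed_values) == {
            "Date", "Time", "Duration", "Frequency"
        }
        assert set(scheme.attribute("DocTime").allowed_values) == {
            "Before", "After", "Overlap", "Before_Overlap"
        }

    def test_medication_attributes(self, scheme):
        med = [
            a.name
            for a in scheme.attributes
            if a.applicable_to == ("Chemicals_Drugs",)
        ]
        assert sorted(med) == [
            "AdministrationRoute", "Dosage", "DrugForm", "Strength"
        ]

    def test_flags_outside_counted_inventory(self, scheme):
        assert {a.name for a in scheme.flag_attributes} == {
            "Abbreviation", "CoreferentPronoun"
        }
        assert all(a.anchoring == "flag" for a in scheme.flag_attributes)


class TestRelationConstraints:
    @pytest.mark.parametrize(
        "relation,src,tgt,expected",
        [
            ("Treats", "Chemicals_Drugs", "Disorder", True),
            ("Causes", "Disorder", "SignOrSymptom", True),
            ("Causes", "SignOrSymptom", "Disorder", True),
            ("Treats", "Anatomy", "Disorder", False),
            ("Measure_of", "Measurement", "Disorder", True),
            ("Measure_of", "Measurement", "Hospital", False),
            ("Localization_of", "Localization", "Hospital", True),
            ("During", "Chemicals_Drugs", "Temporal", True),
            ("During", "Temporal", "Chemicals_Drugs", False),
            ("HasDosage", "Chemicals_Drugs", "Dosage", True),
            ("HasDosage", "Chemicals_Drugs", "Strength", False),
            ("Negation", "Assertion", "Aspect", True),
        ],
    )
    def test_argument_pairs(self, scheme, relation, src, tgt, expected):
        assert scheme.relation_arguments_allowed(relation, src, tgt) is expected

    def test_unknown_names_raise(self, scheme):
        with pytest.raises(UnknownNameError):
            scheme.relation_arguments_allowed("NotARelation", "Disorder", "Disorder")
        with pytest.raises(UnknownNameError):
            scheme.relation_arguments_allowed("Treats", "NotAKind", "Disorder")

    def test_bidirectional_rows_expand_both_ways(self, scheme):
        for rel in ("Causes", "Complicates"):
            pairs = scheme.allowed_pairs_expanded(rel)
            assert ("SignOrSymptom", "Disorder") in pairs
            assert ("Disorder", "SignOrSymptom") in pairs

    def test_directed_rows_stay_directed(self, scheme):
        # Reveals admits SignOrSymptom -> Disorder but not the converse
        assert scheme.relation_arguments_allowed("Reveals", "SignOrSymptom", "Disorder")
        assert not scheme.relation_arguments_allowed("Reveals", "Disorder", "SignOrSymptom")

    def test_referential_closure(self, scheme):
        declared = {e.name for e in scheme.entity_types}
        declared.update(
            a.name for a in scheme.attributes if a.anchoring == "text_anchored"
        )
        for r in scheme.relations:
            for src, tgt in scheme.allowed_pairs_expanded(r.name):
                assert src in declared
                assert tgt in declared

    def test_constraint_index_covers_every_pair(self, scheme):
        idx = scheme.constraint_index()
        assert idx["REL.TREATS.1"] == ("Treats", "Chemicals_Drugs", "Disorder")
        assert len(idx) == sum(len(r.allowed_pairs) for r in scheme.relations)


class TestAttributeApplicability:
    @pytest.mark.parametrize(
        "attribute,target,expected",
        [
            ("DocTime", "Disorder", True),
            ("DocTime", "Concept_Idea", True),
            ("DocTime", "Hospital", False),
            ("TemporalType", "Temporal", True),
            ("TemporalType", "Persons", False),
            ("PersonType", "Persons", True),
            ("PersonType", "LivingBeings", False),
            ("Abbreviation", "Genes_Proteins", True),
            ("CoreferentPronoun", "Persons", True),
            ("CoreferentPronoun", "Disorder", False),
        ],
    )
    def test_examples(self, scheme, attribute, target, expected):
        assert scheme.attribute_applicable(attribute, target) is expected

    def test_unknown_attribute_raises(self, scheme):
        with pytest.raises(UnknownNameError):
            scheme.attribute_applicable("NotAnAttribute", "Disorder")


class TestSemanticTypeMap:
    @pytest.mark.parametrize(
        "sty,expected",
        [
            ("Neoplastic Process", "Disorder"),
            ("Pharmacological Substance", "Chemicals_Drugs"),
            ("Sign or Symptom", "SignOrSymptom"),
            ("Temporal Concept", "Temporal"),
            ("Human", "Persons"),
            ("Findings", None),
            ("Not A Semantic Type", None),
        ],
    )
    def test_lookup(self, scheme, sty, expected):
        assert scheme.map_semantic_type(sty) == expected

    def test_total_over_declared_semantic_types(self, scheme):
        for e in scheme.entity_types:
            for sty in e.umls_semantic_types:
                assert scheme.map_semantic_type(sty) == e.name


class TestAliases:
    @pytest.mark.parametrize(
        "alias,canonical",
        [
            ("Sign/Symptom", "SignOrSymptom"),
            ("Genes/Proteins", "Genes_Proteins"),
            ("Chemical_Drugs", "Chemicals_Drugs"),
            ("BiologicalProcess", "BiologicalProcessOrFunction"),
        ],
    )
    def test_entity_aliases_resolve(self, scheme, alias, canonical):
        assert scheme.canonical_kind(alias) == canonical

    def test_names_are_brat_safe(self, scheme):
        for e in scheme.entity_types:
            assert " " not in e.name and "/" not in e.name


class TestLoadingAndGenericSchemes:
    def test_empty_scheme_summary_is_zero(self):
        s = SchemeDefinition()
        summ = s.summary()
        assert summ.n_entity_types == 0
        assert summ.n_attributes == 0
        assert summ.n_relations == 0
        assert sum(summ.family_counts.values()) == 0

    def test_family_counts_sum_for_arbitrary_scheme(self):
        raw = {
            "entity_types": [{"name": "A", "is_event": True}, {"name": "B"}],
            "relations": [
                {"name": "R1", "family": "temporal", "allowed_pairs": [["A", "B"]]},
                {"name": "R2", "family": "aspect", "allowed_pairs": [["B", "A"]]},
            ],
        }
        s = scheme_from_mapping(raw)
        assert sum(s.summary().family_counts.values()) == s.summary().n_relations == 2

    def test_valued_attribute_without_values_is_rejected(self):
        raw = {
            "entity_types": [{"name": "A"}],
            "attributes": [{"name": "Bad", "anchoring": "valued",
                            "applicable_to": ["A"]}],
        }
        with pytest.raises(SchemeError, match="Bad"):
            scheme_from_mapping(raw)

    def test_unknown_kind_in_pair_is_rejected(self):
        raw = {
            "entity_types": [{"name": "A"}],
            "relations": [{"name": "R", "family": "temporal",
                           "allowed_pairs": [["A", "Nope"]]}],
        }
        with pytest.raises(SchemeError, match="R"):
            scheme_from_mapping(raw)

    def test_default_scheme_loads_deterministically(self):
        a, b = load_default_scheme(), load_default_scheme()
        assert [e.name for e in a.entity_types] == [e.name for e in b.entity_types]
        assert a.semantic_type_map == b.semantic_type_map
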