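"""Inspect the shipped annotation scheme and query its constraints.

The default scheme models clinical narratives with 13 entity types (6 of
which are events), 11 attributes and 37 relations in 5 families.  Relation
argument pairs and attribute applicability are closed-world: anything not
declared is invalid.
"""

from clinscheme import load_default_scheme

scheme = load_default_scheme()
s = scheme.summary()

print(f"entity types : {s.n_entity_types}")
print(f"attributes   : {s.n_attributes}")
print(f"relations    : {s.n_relations}  {dict(s.family_counts)}")
print(f"event types  : {sorted(scheme.event_types)}")

# Constraint lookups: a drug may treat a disorder, an anatomical site may not.
print("Treats(Chemicals_Drugs -> Disorder):",
      scheme.relation_arguments_allowed("Treats", "Chemicals_Drugs", "Disorder"))
print("Treats(Anatomy -> Disorder):       ",
      scheme.relation_arguments_allowed("Treats", "Anatomy", "Disorder"))

# DocTime anchors events to document time; it does not apply to a facility.
print("DocTime on Disorder:", scheme.attribute_applicable("DocTime", "Disorder"))
print("DocTime on Hospital:", scheme.attribute_applicable("DocTime", "Hospital"))

# UMLS semantic types map onto entity categories ('Findings' is unmapped on
# purpose: it produces too many spurious Disorder hits).
print("'Neoplastic Process' ->", scheme.map_semantic_type("Neoplastic Process"))
print("'Findings'           ->", scheme.map_semantic_type("Findings"))
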