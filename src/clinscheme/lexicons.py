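"""Pseudo-clinical French-flavored wordlists for the synthetic corpus generator.

These are template fillers, not natural language: they let generated
documents exercise the representation mechanics (spans, attributes,
relations, temporal expressions) without shipping any clinical text.
"""

from __future__ import annotations

# Fillers per entity type.
DEFAULT_LEXICONS: dict[str, list[str]] = {
    "Anatomy": [
        "foie", "rein gauche", "artère fémorale", "colon", "estomac",
        "poumon droit", "vessie", "rate",
    ],
    "BiologicalProcessOrFunction": [
        "transit", "cicatrisation", "digestion", "coagulation", "respiration",
    ],
    "Chemicals_Drugs": [
        "PARACETAMOL", "AMOXICILLINE", "EPO", "INSULINE", "IBUPROFENE",
        "METFORMINE", "HEPARINE", "OMEPRAZOLE",
    ],
    "Concept_Idea": ["poids", "taille", "score de Glasgow", "stade"],
    "Devices": ["pacemaker", "sonde urinaire", "cathéter", "prothèse de hanche"],
    "Disorder": [
        "diabète", "angine", "cirrhose", "lésion hépatique", "infarctus",
        "pneumopathie", "anémie", "tumeur",
    ],
    "Genes_Proteins": ["fibrine", "hémoglobine", "albumine", "ferritine"],
    "Hospital": [
        "Hôpital Saint-Louis", "CHU de Rouen", "service de gastro-entérologie",
        "urgences",
    ],
    "LivingBeings": ["salmonelle", "Escherichia coli", "candida", "staphylocoque"],
    "MedicalProcedure": [
        "scanner", "coloscopie", "échographie", "biopsie", "consultation",
        "opération", "radiographie",
    ],
    "Persons": ["patient", "patiente", "Dr Martin", "sa mère", "le chirurgien"],
    "SignOrSymptom": [
        "douleur", "fièvre", "toux", "nausées", "vertiges", "céphalées",
    ],
}

# Abbreviated surface forms, eligible for the Abbreviation flag.
ABBREVIATION_LEXICONS: dict[str, list[str]] = {
    "Disorder": ["HTA", "IDM"],
    "Genes_Proteins": ["CRP", "Hb"],
    "MedicalProcedure": ["ECG", "IRM"],
}

# Temporal expressions per TemporalType value. The Duration entries include
# signal-in-span forms ("il y a 5 ans"): the whole expression is one
# temporal mention, signals are not annotated separately.
TEMPORAL_LEXICONS: dict[str, list[str]] = {
    "Date": ["12/04/2012", "janvier 2015", "1984", "le 3 mars"],
    "Time": ["8 h", "minuit", "le matin"],
    "Duration": ["il y a 5 ans", "depuis 3 mois", "pendant 2 semaines"],
    "Frequency": ["deux fois par jour", "toutes les 8 heures", "une fois par semaine"],
}

# Aspect markers and the aspect relation each one signals.
ASPECT_MARKERS: list[tuple[str, str]] = [
    ("introduction de", "Start"),
    ("arrêt de", "Stop"),
    ("reprise de", "Recurrence_StartAgain"),
    ("poursuite de", "Continue"),
    ("majoration de", "Increase"),
    ("diminution de", "Decrease"),
    ("amélioration de", "Improve"),
    ("aggravation de", "Worsen"),
]

# Assertion markers and the assertion relation each one signals.
ASSERTION_MARKERS: list[tuple[str, str]] = [
    ("pas de", "Negation"),
    ("suspicion de", "Possible"),
    ("présence de", "Presence"),
    ("en cas de", "SubjectToCondition"),
]

LOCALIZATION_MARKERS = ["droite", "gauche", "bilatérale", "inférieure"]

# Measurement markers with their subtype.
MEASUREMENT_MARKERS: list[tuple[str, str]] = [
    ("3 cm", "Quantitative"),
    ("120 mmHg", "Quantitative"),
    ("normale", "Qualitative"),
    ("modérée", "Qualitative"),
]

DRUG_ATTRIBUTE_MARKERS: dict[str, list[str]] = {
    "AdministrationRoute": ["par voie orale", "en IV", "par voie cutanée"],
    "Dosage": ["2 comprimés", "une injection", "3 gélules"],
    "DrugForm": ["comprimé", "gélule", "sirop"],
    "Strength": ["500 mg", "10 mg/ml", "1 g"],
}

PRONOUNS = ["Je", "Elle", "Il"]
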