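# Methods

## The scheme as a type system

`SchemeDefinition` pins an annotation scheme down as data: entity types
(with an `is_event` marker, a provenance tag distinguishing UMLS-group
derived categories from added ones, and the UMLS semantic types that map
onto each category), attribute definitions (anchoring ∈ {text_anchored,
valued, flag}, closed value lists, applicability), and relation definitions
(five families; a list of directed allowed argument pairs).  Three wildcard
classes keep the tables compact — `ANY_ENTITY` (all 13 entity types),
`EVENT_ENTITY` (the 6 events), `EVENT_OR_TEMPORAL` (events plus Temporal) —
and are expanded to concrete kinds on lookup.

Decisions taken where the scheme's prose left room:

- **Canonical names are BRAT-safe** (`SignOrSymptom`, `Genes_Proteins`,
  `Chemicals_Drugs`, …); spelling variants seen in the wild
  (`Sign/Symptom`, `Chemical_Drugs`, `BiologicalProcess`) are registered as
  aliases and resolve to the canonical name everywhere.
- **Closed world**: a (relation, source, target) combination absent from
  the transcribed inventory is invalid.  Bidirectional table rows expand to
  two directed pairs at load time; everything else stays strictly directed.
- **Assertion applicability** is read broadly: assertion relations may
  target any entity plus Aspect, Measurement and Localization markers (the
  union of the two places the inventory describes them).
- The **abbreviation** and **coreferent-pronoun** markers are modeled as
  flag attributes held outside the counted inventory of 11, so the printed
  attribute count stays meaningful while both flags remain first-class and
  validated.
- The temporal layer is TimeML-derived but **signals are annotated inside
  the temporal expression** ("il y a 5 ans" is one Duration mention), not
  as separate signal spans.

Every allowed pair carries a stable constraint id (`REL.TREATS.1`, …) via
`SchemeDefinition.constraint_index()` for traceability in reviews.

## Standoff I/O

Offsets are 0-based, half-open, **character** offsets into Unicode text
(French clinical text is accent-heavy; BRAT counts characters).
Discontinuous mentions are ordered fragment lists; their surface is the
covered text joined with single spaces.  Parsing is scheme-agnostic: every
T-line becomes a text-bound annotation, and whether it is an entity mention
or an anchored-attribute marker is decided against the scheme at validation
time.  Anchored attributes are serialized as T-lines and tied to their
targets by relations of their linking family, matching how the scheme
itself models them.  Unknown line types (`#`, `E`, `N`, `*`) pass through
opaquely.  Serialization sorts ids numerically within the T/A/R groups, so
equal documents produce byte-identical files; `parse ∘ write` is the
identity on everything the generator produces.

## Validation

`validate_document` reports every violation (never throws) with a code from
a closed set: `UNKNOWN_TYPE`, `SPAN_BOUNDS`, `REL_ARGS`, `ATTR_TARGET`,
`VALUE_DOMAIN`, `FLAG_SCOPE`, `ANCHORING`, plus the warning-severity
`ANCHOR_LINKED` (a marker participating in no relation of its linking
family).  `ANCHOR_LINKED` is advisory because markers are linked by
convention, not by a stated hard rule.  A missing Presence assertion is
deliberately *not* an issue: when there is no textual marker, no relation
is representable, and bare entities are implicitly asserted present.
Measurement subtypes (Quantitative/Qualitative) are optional metadata.  An
annotation with an unknown type yields exactly one issue; relations whose
endpoint types are unknown are not additionally flagged, so issues do not
cascade.  Reports are deterministic, ordered by (annotation id, code).
Monotonicity (adding an annotation never removes an issue) holds for
error-severity issues; a warning can legitimately disappear when the
missing link is added.

## Agreement

Matching is one-to-one and deterministic.  Strict mode requires identical
fragment lists (and type); overlap mode requires ≥ 1 shared character over
the union of fragments, resolved greedily by maximal overlap length with
ties broken by smaller reference start offset.  On realistic inputs —
mentions that rarely overlap within one annotator's output — the greedy
matching attains the exhaustive-optimal matching size; this is asserted
against a brute-force assignment oracle on all generated documents with at
most 8 mentions.  Adversarially interleaved span sets could in principle
defeat the greedy choice; such configurations do not arise from the
perturbation model and the package makes no claim about them.

Scoring: per-type P = matched/|candidate|, R = matched/|reference|,
F1 = harmonic mean; a type absent from both sides is reported as undefined
(`None`) and skipped by aggregates.  Relations match iff their name and
both matched endpoints agree; valued attributes iff (name, value) agree and
the target is matched.  Corpus agreement pools per-type counts across
documents paired by doc id (micro); macro averages are reported alongside.
Swapping reference and candidate swaps P and R and leaves F1 unchanged.
F-measure is the implemented statistic; chance-corrected coefficients
(kappa) are out of scope.

## Synthetic corpus generator

The generator emulates the sentence patterns of clinical narratives at the
representation level: medication statements (drug + dosage/strength/route
markers + frequency), negated or hedged findings (assertion markers),
therapy status changes (aspect markers + dates), exam findings (procedure →
disorder → anatomical site), measurements, localized symptoms (including
discontinuous mentions such as "douleur … lombaire"), and temporal
anchorings covering all four TemporalType values.  Text is template filler
over French-flavored pseudo-clinical lexicons — deliberately not natural
language: the artifact tests representation mechanics, not linguistics, and
ships no clinical text.

Defaults: 20 documents, a mean of 8 entity mentions per document (Poisson),
relation density 0.9 and attribute density 0.9 (the per-opportunity
emission probabilities), uniform entity-type weights.  These sizes keep
every document a few sentences long — enough for each relation family to
appear while individual documents stay small enough for exhaustive oracles.
A marker is only ever emitted together with its linking relation, and
relations are drawn directly from the allowed-pair inventory, so generated
corpora validate with zero issues (warnings included).  Determinism: each
document has its own RNG stream seeded by (seed, document index), so
corpora are reproducible byte-for-byte and stable under partial generation.

What passing tests on this data do **not** show: robustness to real
tokenization noise, sentence-crossing relations, nested or heavily
overlapping mentions, annotator disagreement about *meaning* rather than
span/type/presence — real corpora exercise all of these.

## Perturbation and violation injection

`perturb` simulates a second annotator with per-annotation deletion, type
swap and span shift (priority in that order when several fire; shifts move
the whole span by ≤ `span_shift_max` characters, staying in bounds, with
surfaces re-extracted so the output is structurally valid).  The exact
applied counts are returned, which yields analytic expectations — with
deletions only, pooled entity recall is exactly 1 − deleted/total and
precision 1.

`inject_violations` plants exactly *n* independently detectable violations:
each action touches a disjoint set of annotations (a relation retyped to a
forbidden pair, a valued attribute given an out-of-domain value or an
inapplicable target, an isolated mention renamed to an unknown type, a span
pushed out of bounds, a coreferent-pronoun flag on a non-Persons mention),
so the validator finds exactly the injected (code, id) labels — no masking.
Requests that cannot be placed are refused with the achievable maximum.
Span-bounds injections cannot be serialized to standoff (the writer refuses
them, and the file could not be re-parsed); the CLI therefore restricts
on-disk injection to the serializable codes.

## Problem sizes and numerical notes

The test suite and the acceptance script use: 100 seeded generator
configurations (soundness), 1000 generated documents (round-trip), 20
documents × deletion rate 0.2 (analytic recall), ~100 small perturbed
document pairs of ≤ 8 mentions (brute-force matching oracle), and injection
counts up to 20 on documents with ~40 mentions.  All arithmetic is exact
counting except the P/R/F ratios (IEEE doubles; the analytic-recall check
agrees to machine epsilon).  Seeds are kept below 2³¹; per-document streams
use `numpy.random.default_rng([seed, index])`.

## Known limitations

- No temporal consistency solving (e.g. cycle detection over
  Before/During chains) and no semantic plausibility checks.
- Coreference is modeled only as the Persons pronoun flag; no resolution.
- No UMLS Metathesaurus access: `map_semantic_type` is an exact-name lookup
  over the shipped table, not CUI normalization.
- BRAT event (E) and normalization (N) lines pass through unvalidated.
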