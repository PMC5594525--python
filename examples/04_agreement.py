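"""Score agreement between a corpus and a simulated second annotator.

The perturbation records exactly how many annotations it deleted, so the
pooled entity recall is known analytically: recall = 1 - deleted/total.
Precision stays 1.0 because deletion-only perturbation adds nothing.
"""

from clinscheme import (
    MatchConfig,
    PerturbationConfig,
    SynthConfig,
    generate_corpus,
    load_default_scheme,
    pairwise_corpus_agreement,
    perturb,
)

scheme = load_default_scheme()
reference = generate_corpus(scheme, SynthConfig(seed=5, n_docs=10))

candidate, total, deleted = [], 0, 0
for i, doc in enumerate(reference):
    p, record = perturb(doc, PerturbationConfig(seed=i, deletion_rate=0.2), scheme)
    candidate.append(p)
    total += record.n_textbounds
    deleted += record.deleted

result = pairwise_corpus_agreement(reference, candidate, MatchConfig("strict"))
m = result.entities.micro
print(f"deleted {deleted} of {total} annotations")
print(f"entity precision = {m.precision:.3f}  (1.0: nothing was invented)")
print(f"entity recall    = {m.recall:.3f}  (expected {1 - deleted/total:.3f})")
print(f"entity F1        = {m.f1:.3f}")
rel = result.relations.micro
print(f"relation F1      = {rel.f1:.3f}  "
      "(relations incident to a deleted mention are lost too)")
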