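"""Parse and re-serialize a BRAT standoff document, including a
discontinuous mention, and emit the BRAT configuration for the scheme.
"""

from clinscheme import generate_brat_conf, load_default_scheme, parse_ann, write_ann

text = "pas de douleur abdominale et lombaire\n"
ann = """\
T1\tAssertion 0 6\tpas de
T2\tSignOrSymptom 7 25\tdouleur abdominale
T3\tSignOrSymptom 7 14;29 37\tdouleur lombaire
A1\tDocTime T2 Overlap
R1\tNegation Arg1:T1 Arg2:T2
"""

doc = parse_ann(ann, text, doc_id="demo")
print(f"parsed {len(doc.textbounds)} text-bound annotations, "
      f"{len(doc.attributes)} attributes, {len(doc.relations)} relations")
for t in doc.textbounds:
    print(f"  {t.id} {t.type:14s} {t.span.fragments} -> {t.surface!r}")

# T3 is discontinuous: two fragments whose covered text is joined by a space.
round_tripped = parse_ann(write_ann(doc), text, "demo")
print("write -> parse round-trip identical:", round_tripped == doc)

conf = generate_brat_conf(load_default_scheme())
print("\nannotation.conf starts with:")
print("\n".join(conf.splitlines()[:6]))
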