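"""Agreement scoring: matching policies, P/R/F bookkeeping, pooled corpora."""

import pytest

from clinscheme import (
    AnnotatedDocument,
    MatchConfig,
    PerturbationConfig,
    SynthConfig,
    TextBound,
    TextSpan,
    compare_documents,
    generate_corpus,
    match_textbounds,
    pairwise_corpus_agreement,
    perturb,
    score,
)

TEXT = "a" * 60


def _doc(mentions, doc_id="d"):
    tbs = [
        TextBound(f"T{i+1}", t, TextSpan.single(s, e), TEXT[s:e])
        for i, (s, e, t) in enumerate(mentions)
    ]
    return AnnotatedDocument(doc_id=doc_id, text=TEXT, textbounds=tbs)


def brute_force_max_matching(reference, candidate, config):
    """Independent oracle: exhaustive optimal one-to-one matching size."""
    def eligible(rt, ct):
        if config.require_type and rt.type != ct.type:
            return False
        if config.span_mode == "strict":
            return rt.span.fragments == ct.span.fragments
        return bool(rt.span.covered_characters() & ct.span.covered_characters())

    refs = reference.textbounds
    cands = candidate.textbounds

    def rec(i, used):
        if i == len(refs):
            return 0
        best = rec(i + 1, used)
        for j, ct in enumerate(cands):
            if j not in used and eligible(refs[i], ct):
                best = max(best, 1 + rec(i + 1, used | {j}))
        return best

    return rec(0, frozenset())


class TestMatching:
    def test_identical_sets_all_match(self):
        a = _doc([(0, 5, "Disorder"), (6, 9, "Anatomy"), (10, 14, "Disorder"),
                  (15, 20, "Persons"), (21, 30, "Temporal")])
        assert len(match_textbounds(a, a)) == 5

    def test_strict_rejects_overlap_accepts(self):
        ref = _doc([(0, 8, "Disorder")])
        cand = _doc([(0, 6, "Disorder")])
        assert match_textbounds(ref, cand, MatchConfig("strict")) == []
        assert match_textbounds(ref, cand, MatchConfig("overlap")) == [("T1", "T1")]

    def test_overlap_requires_same_type_by_default(self):
        ref = _doc([(0, 8, "Disorder")])
        cand = _doc([(0, 8, "Anatomy")])
        assert match_textbounds(ref, cand, MatchConfig("overlap")) == []
        loose = MatchConfig("overlap", require_type=False)
        assert match_textbounds(ref, cand, loose) == [("T1", "T1")]

    def test_different_texts_refused(self):
        a = _doc([(0, 5, "Disorder")])
        b = AnnotatedDocument(doc_id="d", text="b" * 60)
        with pytest.raises(ValueError):
            match_textbounds(a, b)

    def test_greedy_prefers_maximal_overlap(self):
        ref = _doc([(0, 10, "Disorder")])
        cand = _doc([(0, 3, "Disorder"), (2, 10, "Disorder")])
        assert match_textbounds(ref, cand, MatchConfig("overlap")) == [("T1", "T2")]

    def test_strict_matches_subset_of_overlap_matches(self, scheme):
        docs = generate_corpus(scheme, SynthConfig(seed=5, n_docs=6))
        for i, d in enumerate(docs):
            p, _ = perturb(
                d,
                PerturbationConfig(seed=i, deletion_rate=0.2, span_shift_rate=0.4),
                scheme,
            )
            strict = set(match_textbounds(d, p, MatchConfig("strict")))
            overlap = set(match_textbounds(d, p, MatchConfig("overlap")))
            assert strict <= overlap

    @pytest.mark.parametrize("span_mode", ["strict", "overlap"])
    def test_greedy_equals_brute_force_on_small_documents(self, scheme, span_mode):
        cfg = MatchConfig(span_mode)
        checked = 0
        for seed in range(12):
            docs = generate_corpus(
                scheme, SynthConfig(seed=seed, n_docs=2, mean_entities_per_doc=3)
            )
            for i, d in enumerate(docs):
                p, _ = perturb(
                    d,
                    PerturbationConfig(
                        seed=seed * 10 + i, deletion_rate=0.2,
                        type_swap_rate=0.2, span_shift_rate=0.4,
                    ),
                    scheme,
                )
                if len(d.textbounds) > 8 or len(p.textbounds) > 8:
                    continue
                greedy = len(match_textbounds(d, p, cfg))
                assert greedy == brute_force_max_matching(d, p, cfg)
                checked += 1
        assert checked >= 10


class TestScoring:
    def test_identical_documents_score_one(self, scheme, corpus):
        for d in corpus[:3]:
            res = compare_documents(d, d)
            assert res.entities.micro.f1 == 1.0
            if res.relations.micro.n_reference:
                assert res.relations.micro.f1 == 1.0
            if res.attributes.micro.n_reference:
                assert res.attributes.micro.f1 == 1.0

    def test_missing_entity_counts(self):
        ref = _doc([(0, 5, "Disorder"), (6, 9, "Disorder"),
                    (10, 14, "Disorder"), (15, 20, "Disorder")])
        cand = _doc([(0, 5, "Disorder"), (6, 9, "Disorder"), (10, 14, "Disorder")])
        res = compare_documents(ref, cand)
        ts = res.entities.per_type["Disorder"]
        assert ts.recall == 0.75
        assert ts.precision == 1.0

    def test_swap_exchanges_precision_and_recall(self, scheme):
        docs = generate_corpus(scheme, SynthConfig(seed=6, n_docs=4))
        perturbed = [
            perturb(d, PerturbationConfig(seed=i, deletion_rate=0.25), scheme)[0]
            for i, d in enumerate(docs)
        ]
        fwd = pairwise_corpus_agreement(docs, perturbed)
        rev = pairwise_corpus_agreement(perturbed, docs)
        for block in ("entities", "relations", "attributes"):
            f, r = getattr(fwd, block).micro, getattr(rev, block).micro
            assert f.precision == r.recall
            assert f.recall == r.precision
            assert f.f1 == r.f1

    def test_deleting_candidate_annotation_never_increases_recall(self):
        ref = _doc([(0, 5, "Disorder"), (6, 9, "Disorder"), (10, 14, "Anatomy")])
        cand = _doc([(0, 5, "Disorder"), (6, 9, "Disorder"), (10, 14, "Anatomy")])
        full = compare_documents(ref, cand).entities.micro.recall
        shrunk = AnnotatedDocument(
            doc_id="d", text=TEXT, textbounds=cand.textbounds[:-1]
        )
        assert compare_documents(ref, shrunk).entities.micro.recall <= full

    def test_relation_matched_only_with_matched_endpoints(self):
        from clinscheme import Relation

        ref = _doc([(0, 5, "Chemicals_Drugs"), (6, 9, "Disorder")])
        ref.relations.append(Relation("R1", "Treats", "T1", "T2"))
        cand = _doc([(0, 5, "Chemicals_Drugs"), (10, 14, "Disorder")])
        cand.relations.append(Relation("R1", "Treats", "T1", "T2"))
        res = compare_documents(ref, cand)
        assert res.relations.per_type["Treats"].n_matched == 0

    def test_attribute_matched_requires_name_value_and_target(self):
        from clinscheme import Attribute

        ref = _doc([(0, 5, "Disorder")])
        ref.attributes.append(Attribute("A1", "DocTime", "T1", "Before"))
        same = _doc([(0, 5, "Disorder")])
        same.attributes.append(Attribute("A1", "DocTime", "T1", "Before"))
        other_value = _doc([(0, 5, "Disorder")])
        other_value.attributes.append(Attribute("A1", "DocTime", "T1", "After"))
        assert compare_documents(ref, same).attributes.micro.f1 == 1.0
        assert compare_documents(ref, other_value).attributes.micro.f1 == 0.0

    def test_empty_type_reported_undefined_and_skipped(self):
        ref = _doc([])
        cand = _doc([])
        res = score([], ref, cand)
        assert res.entities.micro.f1 is None
        assert res.entities.macro_f1 is None


class TestCorpusAgreement:
    def test_self_agreement_is_one(self, scheme, corpus):
        res = pairwise_corpus_agreement(corpus, corpus)
        assert res.entities.micro.f1 == 1.0
        assert res.relations.micro.f1 == 1.0
        assert res.attributes.micro.f1 == 1.0

    def test_deletion_only_recall_matches_counts(self, scheme):
        docs = generate_corpus(scheme, SynthConfig(seed=7, n_docs=8))
        total = deleted = 0
        perturbed = []
        for i, d in enumerate(docs):
            p, rec = perturb(d, PerturbationConfig(seed=i, deletion_rate=0.3), scheme)
            perturbed.append(p)
            total += rec.n_textbounds
            deleted += rec.deleted
        res = pairwise_corpus_agreement(docs, perturbed)
        assert res.entities.micro.recall == pytest.approx(1 - deleted / total)
        assert res.entities.micro.precision == 1.0

    def test_disjoint_annotation_sets_score_zero(self):
        a = _doc([(0, 5, "Disorder")])
        b = _doc([(10, 14, "Disorder")])
        assert compare_documents(a, b).entities.micro.f1 == 0.0

    def test_missing_counterpart_documents_are_skipped(self, corpus):
        res = pairwise_corpus_agreement(corpus, corpus[:-1])
        assert res.skipped_docs == [corpus[-1].doc_id]
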