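"""TF-IDF cosine normalization of mentions to concept IDs."""

import math
import random
from collections import Counter

import pytest

from disner.lexicon import Lexicon
from disner.normalize import (ConceptNormalizer, build_concept_index,
                              normalize_document, normalize_mention,
                              preprocess_term, rank_concepts)


class TestPreprocessTerm:
    def test_lowercase_stem(self):
        assert preprocess_term("Delirium") == ["delirium"]

    def test_inflection_conflation(self):
        assert preprocess_term("hearing loss") == preprocess_term("Hearing Losses")

    def test_empty_string(self):
        assert preprocess_term("") == []


class TestBuildIndex:
    def test_disjoint_terms_idf(self):
        lex = Lexicon({"A": ("alpha", []), "B": ("beta", [])})
        index = build_concept_index(lex)
        for term, idf in index.idf.items():
            assert idf == pytest.approx(math.log(2))

    def test_ubiquitous_term_contributes_nothing(self):
        lex = Lexicon({"A": ("shared alpha", []), "B": ("shared beta", [])})
        index = build_concept_index(lex)
        shared = preprocess_term("shared")[0]
        assert index.idf[shared] == 0.0
        ranked = rank_concepts("shared", index)
        assert all(score == 0.0 for _, score in ranked)

    def test_hand_computed_tfidf(self):
        lex = Lexicon({"A": ("pain", ["chest pain"]),
                       "B": ("ache", []),
                       "C": ("chest wall", [])}, stem_terms=False)
        index = build_concept_index(lex)
        # df: pain->1 doc, chest->2 docs, ache->1, wall->1; N=3
        assert index.vectors["A"]["pain"] == pytest.approx(2 * math.log(3 / 1))
        assert index.vectors["A"]["chest"] == pytest.approx(1 * math.log(3 / 2))
        assert index.vectors["C"]["wall"] == pytest.approx(math.log(3))

    def test_empty_lexicon_and_empty_concept(self):
        with pytest.raises(ValueError):
            build_concept_index(Lexicon({}))
        with pytest.raises(ValueError, match="X1"):
            Lexicon({"X1": ("...", [])})


class TestRanking:
    def test_exact_single_term_query_scores_one(self):
        lex = Lexicon({"A": ("delirium", []), "B": ("psychosis", [])})
        index = build_concept_index(lex)
        ranked = rank_concepts("delirium", index)
        assert ranked[0] == ("A", pytest.approx(1.0))

    def test_no_overlap_all_zero(self, toy_lexicon):
        index = build_concept_index(toy_lexicon)
        assert all(s == 0.0 for _, s in rank_concepts("zzz qqq", index))

    def test_matches_brute_force_cosine(self):
        rng = random.Random(0)
        vocab = [f"w{i}" for i in range(12)]
        entries = {}
        for k in range(6):
            name = " ".join(rng.choices(vocab, k=rng.randint(1, 4)))
            syns = [" ".join(rng.choices(vocab, k=rng.randint(1, 3)))
                    for _ in range(rng.randint(0, 2))]
            entries[f"C{k}"] = (name, syns)
        lex = Lexicon(entries, stem_terms=False)
        index = build_concept_index(lex)
        n = len(entries)
        df = Counter()
        docs = {}
        for cid in entries:
            counts = Counter(w for t in lex.terms(cid) for w in t.split())
            docs[cid] = counts
            df.update(set(counts))
        for _ in range(30):
            query = " ".join(rng.choices(vocab + ["zzz"], k=rng.randint(1, 4)))
            got = dict(rank_concepts(query, index))
            qc = Counter(query.split())
            qvec = {t: c * math.log(n / df[t]) for t, c in qc.items() if t in df}
            qn = math.sqrt(sum(v * v for v in qvec.values()))
            for cid, counts in docs.items():
                dvec = {t: c * math.log(n / df[t]) for t, c in counts.items()}
                dn = math.sqrt(sum(v * v for v in dvec.values()))
                if qn == 0 or dn == 0:
                    expected = 0.0
                else:
                    expected = sum(v * dvec.get(t, 0.0) for t, v in qvec.items()) / (qn * dn)
                assert abs(got[cid] - expected) < 1e-12

    def test_scores_in_unit_interval(self, synth_lexicon):
        index = build_concept_index(synth_lexicon)
        for cid in synth_lexicon.entries:
            for term in synth_lexicon.terms(cid):
                for _, s in rank_concepts(term, index):
                    assert -1e-12 <= s <= 1.0 + 1e-12


class TestNormalizeMention:
    def test_exact_term_links_with_score_one(self):
        lex = Lexicon({"A": ("delirium", []), "B": ("psychosis", [])})
        index = build_concept_index(lex)
        res = normalize_mention("delirium", index)
        assert res.concept_id == "A" and res.score == pytest.approx(1.0)

    def test_zero_overlap_returns_sentinel(self, toy_lexicon):
        index = build_concept_index(toy_lexicon)
        res = normalize_mention("zzz", index)
        assert res.concept_id == "-1" and res.score == 0.0

    def test_tie_breaks_to_smaller_id(self):
        # identical documents force an exact tie; a third concept keeps
        # the shared terms from having zero idf
        lex = Lexicon({"B2": ("twin disorder", []), "A1": ("twin disorder", []),
                       "C3": ("other thing", [])}, stem_terms=False)
        index = build_concept_index(lex)
        res = normalize_mention("twin disorder", index)
        assert res.concept_id == "A1"

    def test_random_tie_break_is_seeded(self):
        lex = Lexicon({"B2": ("twin disorder", []), "A1": ("twin disorder", []),
                       "C3": ("other thing", [])}, stem_terms=False)
        norm1 = ConceptNormalizer(tie_break="random", seed=3).fit(lex)
        norm2 = ConceptNormalizer(tie_break="random", seed=3).fit(lex)
        q = ["twin disorder"] * 10
        assert norm1.predict(q) == norm2.predict(q)
        assert set(norm1.predict(q)) <= {"A1", "B2"}

    def test_self_retrieval_over_lexicon(self, synth_lexicon):
        index = build_concept_index(synth_lexicon)
        for cid in synth_lexicon.entries:
            for term in synth_lexicon.terms(cid):
                assert normalize_mention(term, index).concept_id == cid

    def test_unrelated_concept_preserves_relative_ranking(self):
        lex = Lexicon({"A": ("alpha pain", []), "B": ("beta ache", [])},
                      stem_terms=False)
        index = build_concept_index(lex)
        before = [cid for cid, _ in rank_concepts("alpha pain", index)]
        lex.add("Z", "zeta cough", [])
        after_index = build_concept_index(lex)
        after = [cid for cid, _ in rank_concepts("alpha pain", after_index)
                 if cid != "Z"]
        assert before == after


class TestNormalizeDocument:
    def test_id_set_semantics(self, synth_lexicon, synth_corpus):
        index = build_concept_index(synth_lexicon)
        for doc in synth_corpus[:6]:
            ids = normalize_document(doc, index)
            expected = set()
            for m in doc.mentions:
                res = normalize_mention(m.surface, index)
                if res.concept_id != "-1":
                    expected.add(res.concept_id)
            assert ids == expected

    def test_all_sentinel_yields_empty_set(self, toy_lexicon):
        from disner.corpus import Document, Mention
        index = build_concept_index(toy_lexicon)
        doc = Document("1", "Zzz qqq", "More zzz.",
                       [Mention(0, 3, "Zzz"), Mention(13, 16, "zzz")])
        assert normalize_document(doc, index) == set()
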