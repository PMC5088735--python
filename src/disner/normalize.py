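"""Vector-space-model concept normalization.

Each concept's preferred name plus synonyms form one "document"; a
recognized mention is a query.  Both sides are lowercased and
Porter-stemmed, weighted with TF-IDF (raw term frequency, idf = ln(N/df),
no smoothing), and ranked by cosine similarity.  The top-ranked concept is
returned; exact score ties resolve to the lexicographically smallest
concept ID by default (a seeded-random mode mirrors a random choice), and
a top score of zero maps to the sentinel "-1".
"""

from __future__ import annotations

import math
import random
from collections import Counter
from dataclasses import dataclass, field

from sklearn.base import BaseEstimator

from .corpus import Document, Mention
from .lexicon import Lexicon, normalize_term


def preprocess_term(text: str, stem: bool = True) -> list[str]:
    """Tokenize on non-alphanumerics, lowercase, Porter-stem."""
    return list(normalize_term(text, stem=stem))


@dataclass
class ConceptIndex:
    """Precomputed TF-IDF vectors over concept synonym-documents."""

    docs: dict[str, Counter]          # concept_id -> stemmed token counts
    idf: dict[str, float]
    vectors: dict[str, dict[str, float]]
    norms: dict[str, float]
    stem: bool = True


def build_concept_index(lexicon: Lexicon) -> ConceptIndex:
    """Index a lexicon: one synonym-expanded document per concept."""
    if not lexicon.entries:
        raise ValueError("empty lexicon")
    docs: dict[str, Counter] = {}
    for cid in lexicon.entries:
        counts: Counter = Counter()
        for term in lexicon.terms(cid):
            counts.update(preprocess_term(term, stem=lexicon.stem_terms))
        if not counts:
            raise ValueError(f"concept {cid}: empty document after preprocessing")
        docs[cid] = counts

    n_docs = len(docs)
    df: Counter = Counter()
    for counts in docs.values():
        df.update(set(counts))
    idf = {term: math.log(n_docs / d) for term, d in df.items()}

    vectors: dict[str, dict[str, float]] = {}
    norms: dict[str, float] = {}
    for cid, counts in docs.items():
        vec = {term: tf * idf[term] for term, tf in counts.items()}
        norm = math.sqrt(sum(w * w for w in vec.values()))
        vectors[cid] = vec
        norms[cid] = norm
    return ConceptIndex(docs=docs, idf=idf, vectors=vectors, norms=norms,
                        stem=lexicon.stem_terms)


def _query_vector(surface: str, index: ConceptIndex) -> tuple[dict[str, float], float]:
    counts = Counter(preprocess_term(surface, stem=index.stem))
    vec = {t: tf * index.idf[t] for t, tf in counts.items() if t in index.idf}
    norm = math.sqrt(sum(w * w for w in vec.values()))
    return vec, norm


def rank_concepts(surface: str, index: ConceptIndex) -> list[tuple[str, float]]:
    """Full concept ranking by cosine similarity, descending; ties order by
    ascending concept ID.  A zero-norm query scores 0 everywhere."""
    qvec, qnorm = _query_vector(surface, index)
    scored = []
    for cid, dvec in index.vectors.items():
        if qnorm == 0.0 or index.norms[cid] == 0.0:
            score = 0.0
        else:
            dot = sum(w * dvec.get(t, 0.0) for t, w in qvec.items())
            score = dot / (qnorm * index.norms[cid])
        scored.append((cid, score))
    scored.sort(key=lambda cs: (-cs[1], cs[0]))
    return scored


@dataclass
class NormalizationResult:
    surface: str
    concept_id: str
    score: float
    candidates: list[tuple[str, float]] = field(default_factory=list)


def normalize_mention(surface_or_mention, index: ConceptIndex,
                      tie_break: str = "id", rng: random.Random | None = None
                      ) -> NormalizationResult:
    """Link one mention to its top-ranked concept; zero top score -> "-1".

    tie_break="id" picks the smallest concept ID among exact ties
    (deterministic); tie_break="random" draws among them using *rng*.
    """
    surface = (surface_or_mention.surface
               if isinstance(surface_or_mention, Mention) else surface_or_mention)
    ranked = rank_concepts(surface, index)
    top_id, top_score = ranked[0]
    if top_score == 0.0:
        return NormalizationResult(surface=surface, concept_id="-1", score=0.0,
                                   candidates=ranked)
    if tie_break == "random":
        ties = [cid for cid, s in ranked if s == top_score]
        top_id = (rng or random).choice(ties)
    return NormalizationResult(surface=surface, concept_id=top_id, score=top_score,
                               candidates=ranked)


def normalize_document(doc: Document, index: ConceptIndex) -> set[str]:
    """Per-document set of linked concept IDs ('-1' excluded), for
    concept-level evaluation."""
    ids = set()
    for mention in doc.mentions:
        res = normalize_mention(mention, index)
        if res.concept_id != "-1":
            ids.add(res.concept_id)
    return ids


def normalize_corpus(docs: list[Document], index: ConceptIndex) -> list[Document]:
    """Copies of *docs* with each mention's concept_id filled in."""
    out = []
    for doc in docs:
        mentions = []
        for m in doc.mentions:
            res = normalize_mention(m, index)
            mentions.append(Mention(start=m.start, end=m.end, surface=m.surface,
                                    type=m.type, concept_id=res.concept_id))
        out.append(Document(doc.doc_id, doc.title, doc.abstract, mentions))
    return out


class ConceptNormalizer(BaseEstimator):
    """Estimator facade: fit on a Lexicon, predict concept IDs for
    mention surfaces."""

    def __init__(self, tie_break: str = "id", seed: int = 0):
        self.tie_break = tie_break
        self.seed = seed

    def fit(self, lexicon: Lexicon, y=None):
        self.index_ = build_concept_index(lexicon)
        self.rng_ = random.Random(self.seed)
        return self

    def predict(self, surfaces: list[str]) -> list[str]:
        return [normalize_mention(s, self.index_, tie_break=self.tie_break,
                                  rng=self.rng_).concept_id
                for s in surfaces]

    def predict_scores(self, surfaces: list[str]) -> list[NormalizationResult]:
        return [normalize_mention(s, self.index_, tie_break=self.tie_break,
                                  rng=self.rng_) for s in surfaces]
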