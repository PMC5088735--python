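"""Document-level base taggers.

These wrap the sentence-level sequence models (:class:`~disner.crf.CRFTagger`,
:class:`~disner.birnn.BiRNNTagger`) behind a common document interface:
``fit`` on gold Documents, ``predict_tokens`` for aligned per-token labels
and confidences, ``tag`` for decoded Mention lists.  The CRF side includes
feature extraction and (optionally) the rule-based post-processing pass;
the Bi-RNN side consumes word embeddings only.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .birnn import BiRNNTagger, EmbeddingTable
from .corpus import (Document, Mention, bio_to_mentions, document_bio,
                     mentions_to_bio, repair_bio, tokenize_document, with_mentions)
from .crf import CRFTagger
from .features import FeatureConfig, SimpleTagger, build_token_features
from .lexicon import Lexicon
from .postprocess import postprocess_mentions


class DictionaryEntityTagger(BaseEstimator):
    """Baseline: greedy longest dictionary-term matching, no learning."""

    def __init__(self, lexicon: Lexicon | None = None):
        self.lexicon = lexicon

    def fit(self, docs: list[Document], y=None):
        return self

    def tag(self, doc: Document) -> list[Mention]:
        from .features import dict_bio
        mentions: list[Mention] = []
        for tokens in tokenize_document(doc):
            labels = dict_bio(tokens, self.lexicon)
            mentions.extend(bio_to_mentions(tokens, labels, doc.full_text))
        return mentions

    def tag_corpus(self, docs: list[Document]) -> list[Document]:
        return [with_mentions(d, self.tag(d)) for d in docs]


class CRFEntityTagger(BaseEstimator):
    """CRF base tagger over documents, with rule-based post-processing.

    Feature extraction uses the bundled POS/chunk tagger unless another
    callable ``tokens -> (pos, chunks)`` is supplied.
    """

    def __init__(self, lexicon: Lexicon | None = None,
                 feature_config: FeatureConfig | None = None,
                 c2: float = 1.0, max_iter: int = 200,
                 postprocess: bool = True, min_count: int = 2,
                 pos_tagger=None):
        self.lexicon = lexicon
        self.feature_config = feature_config
        self.c2 = c2
        self.max_iter = max_iter
        self.postprocess = postprocess
        self.min_count = min_count
        self.pos_tagger = pos_tagger

    def _featurize(self, doc: Document) -> list[tuple[list, list[dict]]]:
        tagger = self.pos_tagger or SimpleTagger()
        out = []
        for tokens in tokenize_document(doc):
            pos, chunks = tagger(tokens)
            fmaps = build_token_features(tokens, pos, chunks, self.lexicon,
                                         self.feature_config)
            out.append((tokens, fmaps))
        return out

    def fit(self, docs: list[Document], y=None):
        X, labels = [], []
        for doc in docs:
            for tokens, fmaps in self._featurize(doc):
                X.append(fmaps)
                labels.append(mentions_to_bio(tokens, doc.mentions))
        self.crf_ = CRFTagger(c2=self.c2, max_iter=self.max_iter).fit(X, labels)
        return self

    def predict_tokens(self, doc: Document):
        """Per-sentence (tokens, labels, confidences); labels are the raw
        Viterbi decode, confidences the posterior marginal of each
        assigned label."""
        out = []
        for tokens, fmaps in self._featurize(doc):
            labels = self.crf_.predict([fmaps])[0]
            marg = self.crf_.predict_marginals([fmaps])[0]
            lab_idx = ["BIO".index(l) for l in labels]
            confs = [float(marg[t, i]) for t, i in enumerate(lab_idx)]
            out.append((tokens, labels, confs))
        return out

    def tag(self, doc: Document) -> list[Mention]:
        """Decode mentions; applies propagation + abbreviation resolution
        when configured."""
        mentions: list[Mention] = []
        for tokens, labels, _ in self.predict_tokens(doc):
            mentions.extend(bio_to_mentions(tokens, repair_bio(labels), doc.full_text))
        if self.postprocess:
            mentions = postprocess_mentions(doc, mentions, self.lexicon,
                                            min_count=self.min_count)
        return mentions

    def tag_corpus(self, docs: list[Document]) -> list[Document]:
        return [with_mentions(d, self.tag(d)) for d in docs]


class BiRNNEntityTagger(BaseEstimator):
    """Bi-RNN base tagger over documents."""

    def __init__(self, hidden_size: int = 32, embed_dim: int = 16,
                 embeddings: EmbeddingTable | None = None, epochs: int = 30,
                 dropout: float = 0.25, lr: float = 1e-3,
                 validation_fraction: float = 0.1, seed: int = 0):
        self.hidden_size = hidden_size
        self.embed_dim = embed_dim
        self.embeddings = embeddings
        self.epochs = epochs
        self.dropout = dropout
        self.lr = lr
        self.validation_fraction = validation_fraction
        self.seed = seed

    def fit(self, docs: list[Document], y=None):
        X, labels = [], []
        for doc in docs:
            for tokens, labs in document_bio(doc):
                X.append([t.surface for t in tokens])
                labels.append(labs)
        self.rnn_ = BiRNNTagger(hidden_size=self.hidden_size,
                                embed_dim=self.embed_dim,
                                embeddings=self.embeddings,
                                epochs=self.epochs, dropout=self.dropout,
                                lr=self.lr,
                                validation_fraction=self.validation_fraction,
                                seed=self.seed).fit(X, labels)
        return self

    def predict_tokens(self, doc: Document):
        out = []
        for tokens in tokenize_document(doc):
            labels, confs = self.rnn_.predict_confidence(
                [[t.surface for t in tokens]])[0]
            out.append((tokens, labels, confs))
        return out

    def penultimate(self, doc: Document) -> list[np.ndarray]:
        """Per-sentence (T, 2H) concatenated hidden-state matrices."""
        return self.rnn_.penultimate(
            [[t.surface for t in tokens] for tokens in tokenize_document(doc)])

    def tag(self, doc: Document) -> list[Mention]:
        mentions: list[Mention] = []
        for tokens, labels, _ in self.predict_tokens(doc):
            mentions.extend(bio_to_mentions(tokens, repair_bio(labels), doc.full_text))
        return mentions

    def tag_corpus(self, docs: list[Document]) -> list[Document]:
        return [with_mentions(d, self.tag(d)) for d in docs]
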