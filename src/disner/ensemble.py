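"""SVM meta-classifier fusing the two base taggers.

Every token is one classification instance.  Its feature vector stacks:
one-hot base-model labels, base-model confidences, each base model's
(constant) cross-validated training error rate, a one-hot POS tag, the two
dictionary look-up features, and the Bi-RNN penultimate-layer vector.
Features are standardized and fed to a multi-class RBF SVM whose
prediction, after BIO repair, yields the final mention list.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, clone
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .corpus import (BIO_LABELS, Document, Mention, bio_to_mentions,
                     document_bio, mentions_to_bio, repair_bio,
                     tokenize_document, with_mentions)
from .features import SimpleTagger, dict_bio, dict_flag
from .lexicon import Lexicon

_LABEL_INDEX = {lab: i for i, lab in enumerate(BIO_LABELS)}


def estimate_error_rates(base_tagger, docs: list[Document], k: int = 5,
                         seed: int = 0) -> float:
    """k-fold cross-validated token-level misclassification rate of a
    document tagger on the training corpus."""
    if k > len(docs):
        raise ValueError(f"k={k} exceeds corpus size {len(docs)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(docs))
    folds = np.array_split(order, k)
    errors = 0
    total = 0
    for fold in folds:
        held = set(fold.tolist())
        train = [docs[i] for i in range(len(docs)) if i not in held]
        test = [docs[i] for i in sorted(held)]
        model = clone(base_tagger).fit(train)
        for doc in test:
            gold = {id(t): lab for tokens, labs in document_bio(doc)
                    for t, lab in zip(tokens, labs)}
            for tokens, labels, _ in model.predict_tokens(doc):
                gold_labs = mentions_to_bio(tokens, doc.mentions)
                errors += sum(1 for a, b in zip(labels, gold_labs) if a != b)
                total += len(tokens)
    return errors / total if total else 0.0


def _mention_bio_for_tokens(doc: Document, mentions: list[Mention],
                            tokens) -> list[str]:
    return mentions_to_bio(tokens, sorted(mentions, key=lambda m: (m.start, m.end)))


def build_instances(doc: Document, crf_output, birnn_output, pos_tags_per_sent,
                    lexicon: Lexicon | None, penultimate_per_sent,
                    error_rates: tuple[float, float],
                    crf_mentions: list[Mention] | None = None,
                    pos_tagset=SimpleTagger.TAGSET,
                    use_embedding_block: bool = True) -> np.ndarray:
    """Per-token ensemble feature matrix for one document.

    crf_output / birnn_output: per-sentence (tokens, labels, confidences)
    from the base taggers.  When *crf_mentions* is given (the
    post-processed CRF mention list), the CRF label block is re-projected
    from those mentions so the combiner sees the post-processed output.
    """
    pos_index = {t: i for i, t in enumerate(pos_tagset)}
    rows = []
    for s, (crf_sent, rnn_sent, pos_tags, penult) in enumerate(
            zip(crf_output, birnn_output, pos_tags_per_sent, penultimate_per_sent)):
        tokens, crf_labels, crf_confs = crf_sent
        r_tokens, rnn_labels, rnn_confs = rnn_sent
        if len(tokens) != len(r_tokens) or len(tokens) != len(pos_tags):
            raise ValueError(f"sentence {s}: misaligned per-token streams")
        if crf_mentions is not None:
            crf_labels = _mention_bio_for_tokens(doc, crf_mentions, tokens)
        flags = [1.0 if (lexicon and dict_flag(t.surface, lexicon) == "Y") else 0.0
                 for t in tokens]
        dbio = dict_bio(tokens, lexicon) if lexicon else ["O"] * len(tokens)
        for t in range(len(tokens)):
            vec = [0.0] * 3
            vec[_LABEL_INDEX[crf_labels[t]]] = 1.0
            rv = [0.0] * 3
            rv[_LABEL_INDEX[rnn_labels[t]]] = 1.0
            pos_vec = [0.0] * len(pos_tagset)
            pos_vec[pos_index.get(pos_tags[t], len(pos_tagset) - 1)] = 1.0
            dbio_vec = [0.0] * 3
            dbio_vec[_LABEL_INDEX[dbio[t]]] = 1.0
            row = (vec + rv
                   + [float(crf_confs[t]), float(rnn_confs[t])]
                   + [float(error_rates[0]), float(error_rates[1])]
                   + pos_vec + [flags[t]] + dbio_vec)
            if use_embedding_block:
                row += [float(x) for x in penult[t]]
            rows.append(row)
    return np.array(rows)


def instance_dimension(pos_tagset=SimpleTagger.TAGSET, hidden_size: int = 32,
                       use_embedding_block: bool = True) -> int:
    """Closed-form ensemble feature dimension."""
    d = 3 + 3 + 2 + 2 + len(pos_tagset) + 1 + 3
    if use_embedding_block:
        d += 2 * hidden_size
    return d


class SVMCombiner(BaseEstimator):
    """Standardize-then-SVC multi-class combiner over token instances."""

    def __init__(self, C: float = 1.0, kernel: str = "rbf",
                 gamma: str | float = "auto", class_weight: str | None = "balanced",
                 seed: int = 0):
        self.C = C
        self.kernel = kernel
        self.gamma = gamma
        self.class_weight = class_weight
        self.seed = seed

    def fit(self, X: np.ndarray, y: list[str]):
        labels = set(y)
        if len(labels) < 2:
            raise ValueError("single-class training set")
        self.model_ = Pipeline([
            ("scale", StandardScaler()),
            ("svc", SVC(C=self.C, kernel=self.kernel, gamma=self.gamma,
                        class_weight=self.class_weight,
                        random_state=self.seed)),
        ]).fit(np.asarray(X), list(y))
        return self

    def predict(self, X: np.ndarray) -> list[str]:
        return list(self.model_.predict(np.asarray(X)))


class EnsembleTagger(BaseEstimator):
    """End-to-end fusion tagger: trains both base models, estimates their
    error rates by document-level cross-validation, and fits the SVM
    combiner on per-token instances."""

    def __init__(self, crf_tagger=None, birnn_tagger=None,
                 lexicon: Lexicon | None = None, combiner: SVMCombiner | None = None,
                 cv_folds: int = 5, seed: int = 0, pos_tagger=None,
                 cv_overrides: dict | None = None):
        self.crf_tagger = crf_tagger
        self.birnn_tagger = birnn_tagger
        self.lexicon = lexicon
        self.combiner = combiner
        self.cv_folds = cv_folds
        self.seed = seed
        self.pos_tagger = pos_tagger
        self.cv_overrides = cv_overrides

    def _doc_instances(self, doc: Document):
        tagger = self.pos_tagger or SimpleTagger()
        crf_out = self.crf_.predict_tokens(doc)
        rnn_out = self.birnn_.predict_tokens(doc)
        pos = [tagger(tokens)[0] for tokens, _, _ in crf_out]
        penult = self.birnn_.penultimate(doc)
        crf_mentions = self.crf_.tag(doc) if self.crf_.postprocess else None
        X = build_instances(doc, crf_out, rnn_out, pos, self.lexicon, penult,
                            (self.crf_error_rate_, self.birnn_error_rate_),
                            crf_mentions=crf_mentions)
        tokens_flat = [t for tokens, _, _ in crf_out for t in tokens]
        return X, tokens_flat, crf_out

    def fit(self, docs: list[Document], y=None):
        from .taggers import BiRNNEntityTagger, CRFEntityTagger
        self.crf_ = clone(self.crf_tagger) if self.crf_tagger is not None \
            else CRFEntityTagger(lexicon=self.lexicon)
        self.birnn_ = clone(self.birnn_tagger) if self.birnn_tagger is not None \
            else BiRNNEntityTagger(seed=self.seed)

        overrides = self.cv_overrides or {}
        cv_crf = clone(self.crf_).set_params(**overrides.get("crf", {}))
        cv_rnn = clone(self.birnn_).set_params(**overrides.get("birnn", {}))
        self.crf_error_rate_ = estimate_error_rates(cv_crf, docs,
                                                    k=self.cv_folds, seed=self.seed)
        self.birnn_error_rate_ = estimate_error_rates(cv_rnn, docs,
                                                      k=self.cv_folds, seed=self.seed)

        self.crf_.fit(docs)
        self.birnn_.fit(docs)

        X_parts, y_parts = [], []
        for doc in docs:
            X, tokens_flat, crf_out = self._doc_instances(doc)
            gold = [lab for tokens, _, _ in crf_out
                    for lab in mentions_to_bio(tokens, doc.mentions)]
            if len(X):
                X_parts.append(X)
                y_parts.extend(gold)
        X_all = np.vstack(X_parts)
        self.combiner_ = clone(self.combiner) if self.combiner is not None else SVMCombiner()
        self.combiner_.fit(X_all, y_parts)
        return self

    def tag(self, doc: Document) -> list[Mention]:
        X, tokens_flat, crf_out = self._doc_instances(doc)
        if not len(X):
            return []
        pred = self.combiner_.predict(X)
        mentions: list[Mention] = []
        pos = 0
        for tokens, _, _ in crf_out:
            labels = repair_bio(pred[pos:pos + len(tokens)])
            mentions.extend(bio_to_mentions(tokens, labels, doc.full_text))
            pos += len(tokens)
        return mentions

    def tag_corpus(self, docs: list[Document]) -> list[Document]:
        return [with_mentions(d, self.tag(d)) for d in docs]


def combine(doc: Document, ensemble: EnsembleTagger) -> list[Mention]:
    """Functional wrapper: final fused mention list for one document."""
    return ensemble.tag(doc)


def train_combiner(instances: np.ndarray, gold_labels: list[str],
                   C: float = 1.0, kernel: str = "rbf", seed: int = 0) -> SVMCombiner:
    return SVMCombiner(C=C, kernel=kernel, seed=seed).fit(instances, gold_labels)
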