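"""Bidirectional RNN token classifier.

Two independent simple recurrences read the sentence's word-embedding
sequence left-to-right and right-to-left:

    h_fwd[t] = f(U_f x_t + W_f h_fwd[t-1] + b_f)
    h_bwd[t] = f(U_b x_t + W_b h_bwd[t+1] + b_b)

and a time-distributed softmax output layer consumes their concatenation:

    y_t = softmax(V [h_fwd[t] ; h_bwd[t]])

over the C = 3 BIO classes.  f is tanh (default) or the logistic sigmoid;
h_fwd[0-] and h_bwd[T+] start at zero.  Training is per-sentence
backpropagation through time with Adam, inverted dropout on the input
embeddings, and a per-epoch validation log-likelihood for convergence
monitoring.  Embedding rows (including a dedicated OOV row) are trained
with the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .corpus import BIO_LABELS

_LABEL_INDEX = {lab: i for i, lab in enumerate(BIO_LABELS)}
N_CLASSES = len(BIO_LABELS)

OOV = "__OOV__"


def softmax(v: np.ndarray) -> np.ndarray:
    """Stable softmax along the last axis (max-shifted)."""
    v = np.asarray(v, dtype=float)
    shifted = v - v.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class EmbeddingTable:
    """token -> D-dimensional vector, with a dedicated OOV vector.

    Lookup lowercases the token.  The text format is one whitespace-
    delimited ``token v1 ... vD`` row per line; an optional leading
    ``count dim`` header is tolerated.
    """

    vectors: dict[str, np.ndarray]
    oov: np.ndarray

    def __post_init__(self) -> None:
        dims = {len(v) for v in self.vectors.values()} | {len(self.oov)}
        if len(dims) != 1:
            raise ValueError(f"inconsistent embedding dimensions: {sorted(dims)}")
        self.dim = len(self.oov)

    def lookup(self, token: str) -> np.ndarray:
        return self.vectors.get(token.lower(), self.oov)

    def __contains__(self, token: str) -> bool:
        return token.lower() in self.vectors

    def to_text(self) -> str:
        lines = []
        for tok in sorted(self.vectors):
            vals = " ".join(repr(float(x)) for x in self.vectors[tok])
            lines.append(f"{tok} {vals}")
        vals = " ".join(repr(float(x)) for x in self.oov)
        lines.append(f"{OOV} {vals}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "EmbeddingTable":
        vectors: dict[str, np.ndarray] = {}
        oov = None
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if lines and len(lines[0].split()) == 2 and all(p.isdigit() for p in lines[0].split()):
            lines = lines[1:]  # count header
        for ln in lines:
            parts = ln.split()
            tok, vec = parts[0], np.array([float(x) for x in parts[1:]])
            if tok == OOV:
                oov = vec
            else:
                vectors[tok] = vec
        if not vectors:
            raise ValueError("empty embedding file")
        if oov is None:
            oov = np.zeros(len(next(iter(vectors.values()))))
        return cls(vectors=vectors, oov=oov)

    @classmethod
    def random(cls, vocab, dim: int, seed: int = 0, scale: float = 0.08) -> "EmbeddingTable":
        rng = np.random.default_rng(seed)
        vocab = sorted({t.lower() for t in vocab})
        vectors = {t: rng.uniform(-scale, scale, dim) for t in vocab}
        return cls(vectors=vectors, oov=rng.uniform(-scale, scale, dim))


def embed_tokens(table: EmbeddingTable, tokens) -> np.ndarray:
    """(T, D) matrix of embedding vectors; unknown tokens get the OOV row."""
    surfaces = [t if isinstance(t, str) else t.surface for t in tokens]
    if not surfaces:
        return np.zeros((0, table.dim))
    return np.stack([table.lookup(s) for s in surfaces])


def embedding_coverage(table: EmbeddingTable, tokens) -> float:
    """Fraction of (lowercased) token types present in the table."""
    types = {(t if isinstance(t, str) else t.surface).lower() for t in tokens}
    if not types:
        return 0.0
    return sum(1 for t in types if t in table.vectors) / len(types)


@dataclass
class BiRNNParams:
    """All learnable matrices of the bidirectional recurrence."""

    U_f: np.ndarray  # (H, D)
    W_f: np.ndarray  # (H, H)
    b_f: np.ndarray  # (H,)
    U_b: np.ndarray
    W_b: np.ndarray
    b_b: np.ndarray
    V: np.ndarray    # (C, 2H)
    activation: str = "tanh"

    def __post_init__(self) -> None:
        if self.activation not in ("tanh", "logistic"):
            raise ValueError(f"unknown activation {self.activation!r}")
        H, D = self.U_f.shape
        if (self.W_f.shape != (H, H) or self.b_f.shape != (H,)
                or self.U_b.shape != (H, D) or self.W_b.shape != (H, H)
                or self.b_b.shape != (H,) or self.V.shape[1] != 2 * H):
            raise ValueError("shape-inconsistent Bi-RNN parameters")

    @property
    def hidden_size(self) -> int:
        return self.U_f.shape[0]

    def arrays(self) -> dict[str, np.ndarray]:
        return {"U_f": self.U_f, "W_f": self.W_f, "b_f": self.b_f,
                "U_b": self.U_b, "W_b": self.W_b, "b_b": self.b_b, "V": self.V}


@dataclass
class BiRNNStates:
    h_fwd: np.ndarray  # (T, H)
    h_bwd: np.ndarray  # (T, H)
    y: np.ndarray      # (T, C), each row a probability vector


def _act(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "tanh":
        return np.tanh(z)
    return 1.0 / (1.0 + np.exp(-z))


def _act_deriv_from_h(h: np.ndarray, kind: str) -> np.ndarray:
    if kind == "tanh":
        return 1.0 - h * h
    return h * (1.0 - h)


def forward_pass(params: BiRNNParams, xs: np.ndarray) -> BiRNNStates:
    """Run both recurrences and the softmax output layer over the input
    sequence xs (T, D).  Dropout is inference-off by definition here."""
    T = len(xs)
    H = params.hidden_size
    h_fwd = np.zeros((T, H))
    h_bwd = np.zeros((T, H))
    h = np.zeros(H)
    for t in range(T):
        h = _act(params.U_f @ xs[t] + params.W_f @ h + params.b_f, params.activation)
        h_fwd[t] = h
    h = np.zeros(H)
    for t in range(T - 1, -1, -1):
        h = _act(params.U_b @ xs[t] + params.W_b @ h + params.b_b, params.activation)
        h_bwd[t] = h
    concat = np.concatenate([h_fwd, h_bwd], axis=1) if T else np.zeros((0, 2 * H))
    y = softmax(concat @ params.V.T) if T else np.zeros((0, params.V.shape[0]))
    return BiRNNStates(h_fwd=h_fwd, h_bwd=h_bwd, y=y)


def _sentence_grads(params: BiRNNParams, xs: np.ndarray, y_idx: np.ndarray):
    """Cross-entropy loss and analytic gradients for one sentence (BPTT).

    Returns (loss, grads dict keyed like params.arrays(), dX (T, D)).
    """
    T = len(xs)
    st = forward_pass(params, xs)
    probs = st.y
    eps = 1e-12
    loss = -float(np.log(probs[np.arange(T), y_idx] + eps).sum())

    dlogits = probs.copy()
    dlogits[np.arange(T), y_idx] -= 1.0  # (T, C)
    H = params.hidden_size
    concat = np.concatenate([st.h_fwd, st.h_bwd], axis=1)
    gV = dlogits.T @ concat
    dcat = dlogits @ params.V  # (T, 2H)
    dhf_out, dhb_out = dcat[:, :H], dcat[:, H:]

    g = {k: np.zeros_like(v) for k, v in params.arrays().items()}
    g["V"] = gV
    dX = np.zeros_like(xs)

    carry = np.zeros(H)
    for t in range(T - 1, -1, -1):
        dh = dhf_out[t] + carry
        dz = dh * _act_deriv_from_h(st.h_fwd[t], params.activation)
        g["U_f"] += np.outer(dz, xs[t])
        h_prev = st.h_fwd[t - 1] if t > 0 else np.zeros(H)
        g["W_f"] += np.outer(dz, h_prev)
        g["b_f"] += dz
        dX[t] += params.U_f.T @ dz
        carry = params.W_f.T @ dz

    carry = np.zeros(H)
    for t in range(T):
        dh = dhb_out[t] + carry
        dz = dh * _act_deriv_from_h(st.h_bwd[t], params.activation)
        g["U_b"] += np.outer(dz, xs[t])
        h_next = st.h_bwd[t + 1] if t < T - 1 else np.zeros(H)
        g["W_b"] += np.outer(dz, h_next)
        g["b_b"] += dz
        dX[t] += params.U_b.T @ dz
        carry = params.W_b.T @ dz

    return loss, g, dX


class BiRNNTagger(BaseEstimator):
    """Bi-RNN BIO tagger with a scikit-learn interface.

    Desk-scale defaults (H=32, D=16) keep training tractable on a single
    CPU; the publication-scale configuration (H=500, D=300) is reachable
    through the same parameters.

    Parameters
    ----------
    hidden_size : per-direction hidden width H.
    embed_dim : embedding dimension D (used when no table is supplied).
    embeddings : optional EmbeddingTable of pre-trained vectors.
    dropout : inverted-dropout rate on input embeddings (training only).
    epochs, lr, beta1, beta2 : Adam-over-BPTT settings, mini-batch size 1.
    validation_fraction : share of training sentences held out for the
        per-epoch validation log-likelihood.
    seed : controls initialization, shuffling and dropout masks; equal
        seeds give bit-identical trajectories.
    """

    def __init__(self, hidden_size: int = 32, embed_dim: int = 16,
                 embeddings: EmbeddingTable | None = None,
                 activation: str = "tanh", dropout: float = 0.25,
                 epochs: int = 30, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, validation_fraction: float = 0.1,
                 init_scale: float = 0.08, seed: int = 0):
        self.hidden_size = hidden_size
        self.embed_dim = embed_dim
        self.embeddings = embeddings
        self.activation = activation
        self.dropout = dropout
        self.epochs = epochs
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.validation_fraction = validation_fraction
        self.init_scale = init_scale
        self.seed = seed

    # --- vocabulary / embedding matrix ---------------------------------

    def _build_vocab(self, X):
        if self.embeddings is not None:
            vocab = sorted(self.embeddings.vectors)
            dim = self.embeddings.dim
        else:
            vocab = sorted({tok.lower() for sent in X for tok in sent})
            dim = self.embed_dim
        self.vocab_ = {tok: i for i, tok in enumerate(vocab)}
        self.oov_index_ = len(vocab)
        return dim

    def _ids(self, sent) -> np.ndarray:
        return np.array([self.vocab_.get(tok.lower(), self.oov_index_) for tok in sent],
                        dtype=int)

    # --- training -------------------------------------------------------

    def fit(self, X, y):
        """X: list of token-surface sequences; y: aligned BIO label lists."""
        if not X:
            raise ValueError("empty training corpus")
        sents = [(list(s), [_LABEL_INDEX[lab] for lab in labs])
                 for s, labs in zip(X, y) if len(s)]
        rng = np.random.default_rng(self.seed)
        D = self._build_vocab(X)
        H = self.hidden_size

        E = rng.uniform(-self.init_scale, self.init_scale, (self.oov_index_ + 1, D))
        if self.embeddings is not None:
            for tok, i in self.vocab_.items():
                E[i] = self.embeddings.vectors[tok]
            E[self.oov_index_] = self.embeddings.oov
        u = lambda *shape: rng.uniform(-self.init_scale, self.init_scale, shape)
        params = BiRNNParams(U_f=u(H, D), W_f=u(H, H), b_f=np.zeros(H),
                             U_b=u(H, D), W_b=u(H, H), b_b=np.zeros(H),
                             V=u(N_CLASSES, 2 * H), activation=self.activation)

        order = rng.permutation(len(sents))
        n_val = int(round(self.validation_fraction * len(sents)))
        val_idx = set(order[:n_val].tolist())
        train_sents = [sents[i] for i in range(len(sents)) if i not in val_idx]
        val_sents = [sents[i] for i in sorted(val_idx)]
        if not train_sents:
            train_sents, val_sents = sents, []

        # Adam state over params + embedding table
        slots = dict(params.arrays())
        slots["E"] = E
        m = {k: np.zeros_like(v) for k, v in slots.items()}
        v2 = {k: np.zeros_like(v) for k, v in slots.items()}
        step = 0

        self.train_loss_history_ = []
        self.val_ll_history_ = []
        for epoch in range(self.epochs):
            perm = rng.permutation(len(train_sents))
            total = 0.0
            n_tok = 0
            for si in perm:
                sent, labs = train_sents[si]
                ids = self._ids(sent)
                xs = E[ids]
                if self.dropout > 0:
                    mask = (rng.random(xs.shape) >= self.dropout) / (1.0 - self.dropout)
                    xs = xs * mask
                else:
                    mask = None
                loss, g, dX = _sentence_grads(params, xs, np.array(labs))
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"NaN/inf loss at epoch {epoch}, sentence {si} "
                        f"(len {len(sent)}); try a lower learning rate")
                total += loss
                n_tok += len(sent)
                gE = np.zeros_like(E)
                dXm = dX if mask is None else dX * mask
                np.add.at(gE, ids, dXm)
                g["E"] = gE

                step += 1
                for k in slots:
                    m[k] = self.beta1 * m[k] + (1 - self.beta1) * g[k]
                    v2[k] = self.beta2 * v2[k] + (1 - self.beta2) * g[k] ** 2
                    mhat = m[k] / (1 - self.beta1 ** step)
                    vhat = v2[k] / (1 - self.beta2 ** step)
                    slots[k] -= self.lr * mhat / (np.sqrt(vhat) + 1e-8)
            self.train_loss_history_.append(total / max(n_tok, 1))
            self.val_ll_history_.append(self._log_likelihood(params, E, val_sents))

        self.params_ = params
        self.E_ = E
        self.classes_ = list(BIO_LABELS)
        return self

    def _log_likelihood(self, params, E, sents) -> float:
        ll = 0.0
        for sent, labs in sents:
            xs = E[self._ids(sent)]
            st = forward_pass(params, xs)
            ll += float(np.log(st.y[np.arange(len(sent)), labs] + 1e-12).sum())
        return ll

    # --- inference -------------------------------------------------------

    def _states(self, sent) -> BiRNNStates:
        xs = self.E_[self._ids(list(sent))]
        return forward_pass(self.params_, xs)

    def predict(self, X):
        """Per-sentence BIO labels: argmax of y_t, ties prefer B < I < O."""
        return [[BIO_LABELS[int(np.argmax(row))] for row in self._states(sent).y]
                for sent in X]

    def predict_marginals(self, X):
        """Per-sentence (T, 3) output distributions y_t."""
        return [self._states(sent).y for sent in X]

    def predict_confidence(self, X):
        """(labels, confidences) per sentence; confidence = max of y_t."""
        out = []
        for sent in X:
            y = self._states(sent).y
            labels = [BIO_LABELS[int(np.argmax(row))] for row in y]
            confs = [float(row.max()) for row in y]
            out.append((labels, confs))
        return out

    def penultimate(self, X):
        """Concatenated hidden states [h_fwd ; h_bwd] per token, dim 2H —
        exactly the vectors the output projection V consumes."""
        out = []
        for sent in X:
            st = self._states(sent)
            out.append(np.concatenate([st.h_fwd, st.h_bwd], axis=1))
        return out

    def loss_and_grad_flat(self, X, y):
        """Total loss and flat gradient over all parameters including the
        embedding table, dropout off — for finite-difference checks."""
        keys = ["U_f", "W_f", "b_f", "U_b", "W_b", "b_b", "V", "E"]
        slots = dict(self.params_.arrays())
        slots["E"] = self.E_
        total = 0.0
        acc = {k: np.zeros_like(v) for k, v in slots.items()}
        for sent, labs in zip(X, y):
            ids = self._ids(list(sent))
            y_idx = np.array([_LABEL_INDEX[lab] for lab in labs])
            loss, g, dX = _sentence_grads(self.params_, self.E_[ids], y_idx)
            total += loss
            for k in g:
                acc[k] += g[k]
            np.add.at(acc["E"], ids, dX)
        flat = np.concatenate([acc[k].ravel() for k in keys])
        return total, flat

    def get_flat_params(self):
        keys = ["U_f", "W_f", "b_f", "U_b", "W_b", "b_b", "V", "E"]
        slots = dict(self.params_.arrays())
        slots["E"] = self.E_
        return np.concatenate([slots[k].ravel() for k in keys])

    def set_flat_params(self, flat):
        keys = ["U_f", "W_f", "b_f", "U_b", "W_b", "b_b", "V", "E"]
        slots = dict(self.params_.arrays())
        slots["E"] = self.E_
        pos = 0
        for k in keys:
            size = slots[k].size
            slots[k][...] = flat[pos:pos + size].reshape(slots[k].shape)
            pos += size


# --- functional wrappers ------------------------------------------------

def train_birnn(corpus, hidden_size: int = 32, embed_dim: int = 16,
                embeddings: EmbeddingTable | None = None, epochs: int = 30,
                dropout_rate: float = 0.25, lr: float = 1e-3,
                seed: int = 0) -> BiRNNTagger:
    """Train from a list of (token surfaces, BIO labels) pairs."""
    X = [s for s, _ in corpus]
    y = [labs for _, labs in corpus]
    return BiRNNTagger(hidden_size=hidden_size, embed_dim=embed_dim,
                       embeddings=embeddings, epochs=epochs,
                       dropout=dropout_rate, lr=lr, seed=seed).fit(X, y)


def tag_with_confidence(model: BiRNNTagger, tokens):
    """(labels, confidences) for one sentence of token surfaces."""
    return model.predict_confidence([tokens])[0]


def penultimate_states(model: BiRNNTagger, tokens) -> np.ndarray:
    return model.penultimate([tokens])[0]


# --- toy skip-gram embeddings ------------------------------------------

def train_toy_embeddings(sentences: list[list[str]], dim: int = 16,
                         window: int = 2, epochs: int = 30, negative: int = 5,
                         lr: float = 0.05, seed: int = 0) -> EmbeddingTable:
    """Skip-gram with negative sampling over a small tokenized corpus.

    A miniature stand-in for large-corpus word2vec training: center-word
    vectors are trained to score true (center, context) pairs above
    frequency-sampled negatives, so words sharing contexts end up close in
    cosine similarity.  Deterministic given the seed.
    """
    if dim <= 0:
        raise ValueError("embedding dimension must be positive")
    rng = np.random.default_rng(seed)
    sents = [[t.lower() for t in s] for s in sentences]
    vocab = sorted({t for s in sents for t in s})
    if not vocab:
        raise ValueError("empty corpus")
    index = {t: i for i, t in enumerate(vocab)}
    counts = np.zeros(len(vocab))
    for s in sents:
        for t in s:
            counts[index[t]] += 1
    noise = counts ** 0.75
    noise /= noise.sum()

    W_in = (rng.random((len(vocab), dim)) - 0.5) / dim
    W_out = np.zeros((len(vocab), dim))

    def sigmoid(x):
        return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))

    for epoch in range(epochs):
        alpha = lr * (1.0 - epoch / epochs) + 1e-4
        for s in sents:
            ids = [index[t] for t in s]
            for pos, center in enumerate(ids):
                lo, hi = max(0, pos - window), min(len(ids), pos + window + 1)
                for ctx_pos in range(lo, hi):
                    if ctx_pos == pos:
                        continue
                    ctx = ids[ctx_pos]
                    negs = rng.choice(len(vocab), size=negative, p=noise)
                    targets = np.concatenate([[ctx], negs])
                    labels = np.zeros(len(targets))
                    labels[0] = 1.0
                    vecs = W_out[targets]
                    scores = sigmoid(vecs @ W_in[center])
                    errs = (scores - labels)[:, None]
                    gin = (errs * vecs).sum(axis=0)
                    W_out[targets] -= alpha * errs * W_in[center]
                    W_in[center] -= alpha * gin
    vectors = {t: W_in[index[t]].copy() for t in vocab}
    oov = rng.uniform(-0.08, 0.08, dim)
    return EmbeddingTable(vectors=vectors, oov=oov)
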