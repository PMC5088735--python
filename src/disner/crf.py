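"""Linear-chain conditional random field over BIO labels.

The model scores a label sequence as the sum of emission weights for every
active ``feature=value`` indicator under the assigned label, plus
transition weights between consecutive labels.  Training maximizes the
L2-regularized conditional log-likelihood with L-BFGS; decoding is
Viterbi; per-token confidences are posterior marginals from
forward-backward.  All sequence computations run in log space and are
batched across sentences (padded to the longest sentence with masking).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.optimize import minimize
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .corpus import BIO_LABELS

_LABEL_INDEX = {lab: i for i, lab in enumerate(BIO_LABELS)}
N_LABELS = len(BIO_LABELS)


def _active_features(fmap: dict[str, str]) -> list[str]:
    return [f"{k}={v}" for k, v in fmap.items()]


class CRFTagger(BaseEstimator):
    """Linear-chain CRF sequence labeller with a scikit-learn interface.

    Parameters
    ----------
    c2 : float
        L2 regularization strength (Gaussian prior precision); the
        objective is NLL + 0.5 * c2 * ||theta||^2.
    max_iter : int
        L-BFGS iteration cap.

    Attributes (after fit)
    ----------------------
    feature_index_ : dict mapping "name=value" strings to column indices
    W_ : ndarray (n_features, 3), emission weights
    T_ : ndarray (3, 3), transition weights, row = previous label
    """

    def __init__(self, c2: float = 1.0, max_iter: int = 200, tol: float = 1e-6):
        self.c2 = c2
        self.max_iter = max_iter
        self.tol = tol

    # --- encoding ------------------------------------------------------

    def _index_features(self, X):
        index: dict[str, int] = {}
        for sent in X:
            for fmap in sent:
                for feat in _active_features(fmap):
                    if feat not in index:
                        index[feat] = len(index)
        return index

    def _encode_matrix(self, X, index):
        """CSR indicator matrix, one row per token over all sentences."""
        indptr = [0]
        indices: list[int] = []
        for sent in X:
            for fmap in sent:
                cols = sorted(index[f] for f in _active_features(fmap) if f in index)
                indices.extend(cols)
                indptr.append(len(indices))
        data = np.ones(len(indices))
        n_rows = indptr and len(indptr) - 1 or 0
        n_cols = max(len(index), 1)
        return sp.csr_matrix((data, indices, indptr), shape=(n_rows, n_cols))

    def _emissions(self, X, W=None):
        """Padded emission score tensor (S, Tmax, 3) plus lengths."""
        W = self.W_ if W is None else W
        lengths = np.array([len(s) for s in X], dtype=int)
        mat = self._encode_matrix(X, self.feature_index_)
        scores = np.asarray(mat @ W)  # (total_tokens, 3)
        Tmax = int(lengths.max()) if len(lengths) else 0
        emis = np.zeros((len(X), Tmax, N_LABELS))
        pos = 0
        for s, L in enumerate(lengths):
            emis[s, :L] = scores[pos:pos + L]
            pos += L
        return emis, lengths

    # --- fitting -------------------------------------------------------

    def fit(self, X, y):
        """Fit on sentences: X is a list of lists of feature dicts, y the
        aligned list of BIO label lists."""
        if not X:
            raise ValueError("empty training corpus")
        for sent, labs in zip(X, y):
            if len(sent) != len(labs):
                raise ValueError("feature maps and labels misaligned")
        X = [s for s in X if s]
        y = [l for l in y if l]
        self.feature_index_ = self._index_features(X)
        n_feat = max(len(self.feature_index_), 1)

        mat = self._encode_matrix(X, self.feature_index_)
        lengths = np.array([len(s) for s in X], dtype=int)
        y_idx = [np.array([_LABEL_INDEX[lab] for lab in labs], dtype=int) for labs in y]

        # observed sufficient statistics
        flat_y = np.concatenate(y_idx)
        Y_onehot = np.zeros((len(flat_y), N_LABELS))
        Y_onehot[np.arange(len(flat_y)), flat_y] = 1.0
        obs_trans = np.zeros((N_LABELS, N_LABELS))
        for labs in y_idx:
            for a, b in zip(labs[:-1], labs[1:]):
                obs_trans[a, b] += 1.0
        n_params = n_feat * N_LABELS + N_LABELS * N_LABELS

        def unpack(theta):
            W = theta[: n_feat * N_LABELS].reshape(n_feat, N_LABELS)
            T = theta[n_feat * N_LABELS:].reshape(N_LABELS, N_LABELS)
            return W, T

        Tmax = int(lengths.max())
        S = len(X)
        # token row offsets per sentence
        offsets = np.concatenate([[0], np.cumsum(lengths)])

        def objective(theta):
            W, T = unpack(theta)
            scores = np.asarray(mat @ W)
            emis = np.zeros((S, Tmax, N_LABELS))
            for s in range(S):
                emis[s, : lengths[s]] = scores[offsets[s]:offsets[s + 1]]
            logZ, post, exp_trans = _forward_backward(emis, lengths, T)

            gold_score = 0.0
            for s in range(S):
                labs = y_idx[s]
                gold_score += scores[offsets[s]:offsets[s + 1]][np.arange(lengths[s]), labs].sum()
                gold_score += T[labs[:-1], labs[1:]].sum()

            nll = logZ.sum() - gold_score
            # expected minus observed feature counts
            post_flat = np.concatenate([post[s, : lengths[s]] for s in range(S)])
            g_emit = np.asarray(mat.T @ (post_flat - Y_onehot))
            g_trans = exp_trans - obs_trans
            nll += 0.5 * self.c2 * float(theta @ theta)
            grad = np.concatenate([g_emit.ravel(), g_trans.ravel()]) + self.c2 * theta
            return nll, grad

        theta0 = np.zeros(n_params)
        res = minimize(objective, theta0, jac=True, method="L-BFGS-B",
                       options={"maxiter": self.max_iter, "ftol": self.tol, "gtol": 1e-8})
        self.W_, self.T_ = unpack(res.x)
        self.n_iter_ = int(res.nit)
        self.final_nll_ = float(res.fun)
        return self

    # --- inference -----------------------------------------------------

    def predict(self, X):
        """Viterbi-decode each sentence; ties prefer B < I < O."""
        out = []
        for sent in X:
            if not sent:
                out.append([])
                continue
            emis, lengths = self._emissions([sent])
            path = _viterbi(emis[0, : lengths[0]], self.T_)
            out.append([BIO_LABELS[i] for i in path])
        return out

    def predict_marginals(self, X):
        """Per-token posterior distributions over (B, I, O), one (T, 3)
        array per sentence; rows sum to 1."""
        out = []
        for sent in X:
            if not sent:
                out.append(np.zeros((0, N_LABELS)))
                continue
            emis, lengths = self._emissions([sent])
            _, post, _ = _forward_backward(emis, lengths, self.T_)
            p = post[0, : lengths[0]]
            out.append(p / p.sum(axis=1, keepdims=True))
        return out

    def nll_and_grad(self, X, y, theta=None):
        """Objective access for gradient checking (regularization included)."""
        if getattr(self, "feature_index_", None) is None:
            self.feature_index_ = self._index_features(X)
        n_feat = max(len(self.feature_index_), 1)
        if theta is None:
            theta = np.concatenate([self.W_.ravel(), self.T_.ravel()])
        mat = self._encode_matrix(X, self.feature_index_)
        lengths = np.array([len(s) for s in X], dtype=int)
        y_idx = [np.array([_LABEL_INDEX[lab] for lab in labs], dtype=int) for labs in y]
        flat_y = np.concatenate(y_idx)
        Y_onehot = np.zeros((len(flat_y), N_LABELS))
        Y_onehot[np.arange(len(flat_y)), flat_y] = 1.0
        obs_trans = np.zeros((N_LABELS, N_LABELS))
        for labs in y_idx:
            for a, b in zip(labs[:-1], labs[1:]):
                obs_trans[a, b] += 1.0
        W = theta[: n_feat * N_LABELS].reshape(n_feat, N_LABELS)
        T = theta[n_feat * N_LABELS:].reshape(N_LABELS, N_LABELS)
        scores = np.asarray(mat @ W)
        S = len(X)
        Tmax = int(lengths.max())
        offsets = np.concatenate([[0], np.cumsum(lengths)])
        emis = np.zeros((S, Tmax, N_LABELS))
        for s in range(S):
            emis[s, : lengths[s]] = scores[offsets[s]:offsets[s + 1]]
        logZ, post, exp_trans = _forward_backward(emis, lengths, T)
        gold = 0.0
        for s in range(S):
            labs = y_idx[s]
            gold += scores[offsets[s]:offsets[s + 1]][np.arange(lengths[s]), labs].sum()
            gold += T[labs[:-1], labs[1:]].sum()
        nll = logZ.sum() - gold + 0.5 * self.c2 * float(theta @ theta)
        post_flat = np.concatenate([post[s, : lengths[s]] for s in range(S)])
        g_emit = np.asarray(mat.T @ (post_flat - Y_onehot))
        grad = np.concatenate([g_emit.ravel(), (exp_trans - obs_trans).ravel()]) + self.c2 * theta
        return nll, grad


# --- core sequence algorithms ------------------------------------------

def _forward_backward(emis: np.ndarray, lengths: np.ndarray, trans: np.ndarray):
    """Batched log-space forward-backward.

    Returns (logZ per sentence, unary posteriors (S, Tmax, 3) valid for
    t < length, expected transition counts (3, 3) summed over the batch).
    """
    S, Tmax, L = emis.shape
    alpha = np.zeros((S, Tmax, L))
    alpha[:, 0] = emis[:, 0]
    for t in range(1, Tmax):
        prev = alpha[:, t - 1]
        upd = emis[:, t] + logsumexp(prev[:, :, None] + trans[None], axis=1)
        active = (t < lengths)[:, None]
        alpha[:, t] = np.where(active, upd, prev)
    logZ = logsumexp(alpha[:, -1] if Tmax else np.zeros((S, L)), axis=1)

    beta = np.zeros((S, Tmax, L))
    for t in range(Tmax - 2, -1, -1):
        nxt = emis[:, t + 1] + beta[:, t + 1]
        upd = logsumexp(trans[None] + nxt[:, None, :], axis=2)
        beta[:, t] = np.where((t < lengths - 1)[:, None], upd, 0.0)

    post = np.exp(alpha + beta - logZ[:, None, None])
    mask = np.arange(Tmax)[None, :] < lengths[:, None]
    post *= mask[:, :, None]

    exp_trans = np.zeros((L, L))
    for t in range(1, Tmax):
        valid = t < lengths
        if not valid.any():
            break
        M = (alpha[:, t - 1, :, None] + trans[None]
             + (emis[:, t] + beta[:, t])[:, None, :] - logZ[:, None, None])
        exp_trans += np.exp(M[valid]).sum(axis=0)
    return logZ, post, exp_trans


def _viterbi(emis: np.ndarray, trans: np.ndarray) -> list[int]:
    """Max-sum decoding for one sentence; argmax ties take the smallest
    label index (B < I < O)."""
    T, L = emis.shape
    if T == 0:
        return []
    delta = emis[0].copy()
    back = np.zeros((T, L), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + trans  # (prev, cur)
        back[t] = np.argmax(cand, axis=0)
        delta = emis[t] + np.max(cand, axis=0)
    path = [int(np.argmax(delta))]
    for t in range(T - 1, 0, -1):
        path.append(int(back[t, path[-1]]))
    return path[::-1]


# --- thin functional wrappers ------------------------------------------

def score_sequence(model: CRFTagger, fmaps: list[dict], labels: list[str]) -> float:
    """Linear-chain potential of one labelling under a fitted model."""
    if len(fmaps) != len(labels):
        raise ValueError("length mismatch")
    for lab in labels:
        if lab not in _LABEL_INDEX:
            raise ValueError(f"unknown label {lab!r}")
    score = 0.0
    idx = model.feature_index_
    for fmap, lab in zip(fmaps, labels):
        li = _LABEL_INDEX[lab]
        for feat in _active_features(fmap):
            if feat in idx:
                score += model.W_[idx[feat], li]
    for a, b in zip(labels[:-1], labels[1:]):
        score += model.T_[_LABEL_INDEX[a], _LABEL_INDEX[b]]
    return float(score)


def viterbi_decode(model: CRFTagger, fmaps: list[dict]) -> list[str]:
    return model.predict([fmaps])[0]


def token_marginals(model: CRFTagger, fmaps: list[dict]) -> np.ndarray:
    return model.predict_marginals([fmaps])[0]


def train_crf(corpus, c2: float = 1.0, max_iter: int = 200) -> CRFTagger:
    """Train from a list of (feature maps, label sequence) pairs."""
    if not corpus:
        raise ValueError("empty corpus")
    X = [fm for fm, _ in corpus]
    y = [labs for _, labs in corpus]
    return CRFTagger(c2=c2, max_iter=max_iter).fit(X, y)
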