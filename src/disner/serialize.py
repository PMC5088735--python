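"""Versioned JSON checkpoints for trained models.

All artifacts are plain text (JSON): weight matrices as nested lists, the
CRF feature index, the Bi-RNN vocabulary, and the combiner's scaling
parameters plus support-vector expansion.  Equal training runs therefore
produce byte-identical files.  Each checkpoint carries a format version
and, for the combiner, a feature-layout manifest so instance-layout
mismatches fail loudly at load time.
"""

from __future__ import annotations

import json

import numpy as np

from .birnn import BiRNNParams, BiRNNTagger
from .crf import CRFTagger
from .ensemble import SVMCombiner, instance_dimension
from .features import FeatureConfig
from .lexicon import Lexicon
from .taggers import BiRNNEntityTagger, CRFEntityTagger

FORMAT_VERSION = 1


def _dump(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True, indent=1)
        fh.write("\n")


def _load(path) -> dict:
    with open(path) as fh:
        obj = json.load(fh)
    if obj.get("format_version") != FORMAT_VERSION:
        raise ValueError(f"{path}: unsupported checkpoint version {obj.get('format_version')}")
    return obj


# --- CRF ------------------------------------------------------------------

def save_crf(tagger: CRFEntityTagger, path) -> None:
    crf = tagger.crf_
    _dump({
        "format_version": FORMAT_VERSION,
        "kind": "crf",
        "params": {"c2": tagger.c2, "max_iter": tagger.max_iter,
                   "postprocess": tagger.postprocess, "min_count": tagger.min_count},
        "feature_config": (vars(tagger.feature_config) | {"affix_lengths": sorted(tagger.feature_config.affix_lengths)}
                           if tagger.feature_config else None),
        "lexicon": tagger.lexicon.to_tsv() if tagger.lexicon else None,
        "feature_index": crf.feature_index_,
        "W": crf.W_.tolist(),
        "T": crf.T_.tolist(),
    }, path)


def load_crf(path) -> CRFEntityTagger:
    obj = _load(path)
    fc = obj["feature_config"]
    if fc:
        fc = FeatureConfig(**{**fc, "affix_lengths": frozenset(fc["affix_lengths"])})
    lexicon = Lexicon.from_tsv(obj["lexicon"]) if obj["lexicon"] else None
    tagger = CRFEntityTagger(lexicon=lexicon, feature_config=fc, **obj["params"])
    crf = CRFTagger(c2=obj["params"]["c2"], max_iter=obj["params"]["max_iter"])
    crf.feature_index_ = obj["feature_index"]
    crf.W_ = np.array(obj["W"])
    crf.T_ = np.array(obj["T"])
    tagger.crf_ = crf
    return tagger


# --- Bi-RNN ---------------------------------------------------------------

def save_birnn(tagger: BiRNNEntityTagger, path) -> None:
    rnn = tagger.rnn_
    _dump({
        "format_version": FORMAT_VERSION,
        "kind": "birnn",
        "params": {"hidden_size": tagger.hidden_size, "embed_dim": tagger.embed_dim,
                   "epochs": tagger.epochs, "dropout": tagger.dropout,
                   "lr": tagger.lr, "seed": tagger.seed,
                   "validation_fraction": tagger.validation_fraction},
        "activation": rnn.params_.activation,
        "vocab": rnn.vocab_,
        "E": rnn.E_.tolist(),
        "weights": {k: v.tolist() for k, v in rnn.params_.arrays().items()},
    }, path)


def load_birnn(path) -> BiRNNEntityTagger:
    obj = _load(path)
    tagger = BiRNNEntityTagger(**obj["params"])
    rnn = BiRNNTagger(hidden_size=obj["params"]["hidden_size"],
                      embed_dim=obj["params"]["embed_dim"],
                      seed=obj["params"]["seed"])
    rnn.vocab_ = dict(obj["vocab"])
    rnn.oov_index_ = len(rnn.vocab_)
    rnn.E_ = np.array(obj["E"])
    w = {k: np.array(v) for k, v in obj["weights"].items()}
    rnn.params_ = BiRNNParams(activation=obj["activation"], **w)
    rnn.classes_ = ["B", "I", "O"]
    tagger.rnn_ = rnn
    return tagger


# --- SVM combiner -----------------------------------------------------------

def save_combiner(combiner: SVMCombiner, path, hidden_size: int) -> None:
    scaler = combiner.model_.named_steps["scale"]
    svc = combiner.model_.named_steps["svc"]
    _dump({
        "format_version": FORMAT_VERSION,
        "kind": "svm_combiner",
        "params": {"C": combiner.C, "kernel": combiner.kernel,
                   "gamma": combiner.gamma, "class_weight": combiner.class_weight,
                   "seed": combiner.seed},
        "layout": {"dimension": instance_dimension(hidden_size=hidden_size),
                   "hidden_size": hidden_size},
        "scaler": {"mean": scaler.mean_.tolist(), "scale": scaler.scale_.tolist()},
        "svc": {
            "classes": [str(c) for c in svc.classes_],
            "gamma_value": float(svc._gamma),
            "support_vectors": svc.support_vectors_.tolist(),
            "dual_coef": svc.dual_coef_.tolist(),
            "intercept": svc.intercept_.tolist(),
            "n_support": svc.n_support_.tolist(),
        },
    }, path)


class _ReloadedSVC:
    """RBF one-vs-one voting predictor rebuilt from stored arrays."""

    def __init__(self, obj: dict):
        self.classes = np.array(obj["classes"])
        self.gamma = obj["gamma_value"]
        self.SV = np.array(obj["support_vectors"])
        self.dual_coef = np.array(obj["dual_coef"])
        self.intercept = np.array(obj["intercept"])
        self.starts = np.concatenate([[0], np.cumsum(obj["n_support"])])

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        K = np.exp(-self.gamma * ((X[:, None, :] - self.SV[None]) ** 2).sum(-1))
        n_cls = len(self.classes)
        votes = np.zeros((len(X), n_cls), dtype=int)
        p = 0
        st = self.starts
        for i in range(n_cls):
            for j in range(i + 1, n_cls):
                ci = self.dual_coef[j - 1, st[i]:st[i + 1]]
                cj = self.dual_coef[i, st[j]:st[j + 1]]
                dec = (K[:, st[i]:st[i + 1]] @ ci + K[:, st[j]:st[j + 1]] @ cj
                       + self.intercept[p])
                votes[np.arange(len(X)), np.where(dec > 0, i, j)] += 1
                p += 1
        return self.classes[np.argmax(votes, axis=1)]


class _ReloadedCombiner:
    def __init__(self, obj: dict):
        self.mean = np.array(obj["scaler"]["mean"])
        self.scale = np.array(obj["scaler"]["scale"])
        self.svc = _ReloadedSVC(obj["svc"])
        self.layout = obj["layout"]

    def predict(self, X) -> list[str]:
        X = np.asarray(X)
        if X.shape[1] != self.layout["dimension"]:
            raise ValueError(
                f"instance dimension {X.shape[1]} does not match the stored "
                f"feature layout ({self.layout['dimension']})")
        return list(self.svc.predict((X - self.mean) / self.scale))


def load_combiner(path):
    obj = _load(path)
    if obj["params"]["kernel"] != "rbf":
        raise ValueError("only RBF combiner checkpoints are reloadable")
    return _ReloadedCombiner(obj)
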