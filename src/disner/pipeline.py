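"""End-to-end pipeline: generate/load corpus, train base taggers, fuse,
normalize, evaluate, and write a reproducibility report.

The config is a plain dict (or JSON file) merged over defaults; every
random decision derives from ``seed``.  Artifacts written per run: the
train/test PubTator files, the lexicon TSV, model checkpoints, tagged and
normalized corpora, and ``report.json`` with both metric levels and the
full resolved config (no timestamps, so equal runs are byte-identical).
"""

from __future__ import annotations

import copy
import json
from pathlib import Path

from .birnn import train_toy_embeddings
from .corpus import Document, tokenize_document, write_pubtator, with_mentions
from .ensemble import EnsembleTagger, SVMCombiner
from .evaluate import evaluate_concepts, evaluate_mentions
from .lexicon import Lexicon
from .normalize import build_concept_index, normalize_corpus
from .synthetic import GeneratorConfig, generate_corpus, make_lexicon, split_corpus
from .taggers import BiRNNEntityTagger, CRFEntityTagger

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "generator": {"n_docs": 300, "lexicon_size": 30},
    "split": [2 / 3, 0.0, 1 / 3],
    "embeddings": "toy",        # "toy" | "random" | path to a text table
    "crf": {"c2": 1.0, "max_iter": 100},
    "birnn": {"hidden_size": 32, "embed_dim": 16, "epochs": 25,
              "dropout": 0.25, "lr": 3e-3},
    "ensemble": {"cv_folds": 3,
                 "cv_overrides": {"crf": {"max_iter": 50}, "birnn": {"epochs": 8}}},
    "postprocess_min_count": 2,
}


def resolve_config(config: dict | str | Path | None) -> dict:
    """Merge a user config (dict or JSON file path) over the defaults."""
    resolved = copy.deepcopy(DEFAULT_CONFIG)
    if config is None:
        return resolved
    if not isinstance(config, dict):
        with open(config) as fh:
            config = json.load(fh)
    for key, val in config.items():
        if isinstance(val, dict) and isinstance(resolved.get(key), dict):
            resolved[key].update(val)
        else:
            resolved[key] = val
    return resolved


def _build_embeddings(kind, train_docs, dim, seed):
    from .birnn import EmbeddingTable
    if kind is None or kind == "random":
        return None  # BiRNNTagger random-initializes over the training vocab
    if kind == "toy":
        sentences = [[t.surface for t in toks]
                     for doc in train_docs for toks in tokenize_document(doc)]
        return train_toy_embeddings(sentences, dim=dim, epochs=5, seed=seed)
    return EmbeddingTable.from_text(Path(kind).read_text())


def build_ensemble(cfg: dict, lexicon: Lexicon, embeddings=None) -> EnsembleTagger:
    seed = cfg["seed"]
    crf = CRFEntityTagger(lexicon=lexicon, min_count=cfg["postprocess_min_count"],
                          **cfg["crf"])
    birnn = BiRNNEntityTagger(embeddings=embeddings, seed=seed, **cfg["birnn"])
    return EnsembleTagger(crf_tagger=crf, birnn_tagger=birnn, lexicon=lexicon,
                          combiner=SVMCombiner(seed=seed), seed=seed,
                          cv_folds=cfg["ensemble"]["cv_folds"],
                          cv_overrides=cfg["ensemble"]["cv_overrides"])


def run_pipeline(config: dict | str | Path | None = None,
                 output_dir: str | Path | None = None,
                 train_docs: list[Document] | None = None,
                 test_docs: list[Document] | None = None,
                 lexicon: Lexicon | None = None) -> dict:
    """Execute the full train -> tag -> post-process -> fuse -> normalize ->
    evaluate pipeline and return the report dict.

    Without explicit corpora, a synthetic corpus is generated and split
    according to the config.  Any stage failure propagates with the stage
    name prefixed.
    """
    cfg = resolve_config(config)
    seed = cfg["seed"]

    stage = "generate"
    try:
        if train_docs is None or lexicon is None:
            gen = GeneratorConfig(seed=seed, **cfg["generator"])
            lexicon = make_lexicon(gen)
            docs = generate_corpus(lexicon, gen)
            train_docs, _dev, test_docs = split_corpus(docs, tuple(cfg["split"]),
                                                       seed=seed)
        if test_docs is None:
            raise ValueError("test_docs required when passing explicit corpora")

        stage = "embeddings"
        embeddings = _build_embeddings(cfg["embeddings"], train_docs,
                                       cfg["birnn"]["embed_dim"], seed)

        stage = "train"
        ensemble = build_ensemble(cfg, lexicon, embeddings)
        ensemble.fit(train_docs)

        stage = "tag"
        crf_raw_docs = []
        for doc in test_docs:
            mentions = []
            for tokens, labels, _ in ensemble.crf_.predict_tokens(doc):
                from .corpus import bio_to_mentions, repair_bio
                mentions.extend(bio_to_mentions(tokens, repair_bio(labels),
                                                doc.full_text))
            crf_raw_docs.append(with_mentions(doc, mentions))
        crf_docs = ensemble.crf_.tag_corpus(test_docs)
        birnn_docs = ensemble.birnn_.tag_corpus(test_docs)
        fused_docs = ensemble.tag_corpus(test_docs)

        stage = "postprocess-monotonicity"
        recall_before = evaluate_mentions(crf_raw_docs, test_docs).recall
        recall_after = evaluate_mentions(crf_docs, test_docs).recall
        if recall_after < recall_before - 1e-12:
            raise AssertionError(
                f"post-processing lowered recall: {recall_before:.4f} -> {recall_after:.4f}")

        stage = "normalize"
        index = build_concept_index(lexicon)
        normalized_docs = normalize_corpus(fused_docs, index)

        stage = "evaluate"
        report = {
            "config": cfg,
            "sizes": {"train_docs": len(train_docs), "test_docs": len(test_docs),
                      "lexicon": len(lexicon.entries)},
            "error_rates": {"crf": ensemble.crf_error_rate_,
                            "birnn": ensemble.birnn_error_rate_},
            "mention_level": {
                "crf": evaluate_mentions(crf_docs, test_docs).as_dict(),
                "crf_pre_postprocess": evaluate_mentions(crf_raw_docs, test_docs).as_dict(),
                "birnn": evaluate_mentions(birnn_docs, test_docs).as_dict(),
                "ensemble": evaluate_mentions(fused_docs, test_docs).as_dict(),
            },
            "concept_level": {
                "ensemble": evaluate_concepts(normalized_docs, test_docs).as_dict(),
            },
        }

        stage = "write"
        if output_dir is not None:
            out = Path(output_dir)
            out.mkdir(parents=True, exist_ok=True)
            (out / "train.pubtator").write_text(write_pubtator(train_docs))
            (out / "test.pubtator").write_text(write_pubtator(test_docs))
            (out / "lexicon.tsv").write_text(lexicon.to_tsv())
            (out / "tagged.pubtator").write_text(write_pubtator(fused_docs))
            (out / "normalized.pubtator").write_text(write_pubtator(normalized_docs))
            from .serialize import save_birnn, save_combiner, save_crf
            save_crf(ensemble.crf_, out / "crf.json")
            save_birnn(ensemble.birnn_, out / "birnn.json")
            save_combiner(ensemble.combiner_, out / "combiner.json",
                          hidden_size=cfg["birnn"]["hidden_size"])
            (out / "report.json").write_text(
                json.dumps(report, sort_keys=True, indent=2) + "\n")
        return report
    except Exception as exc:
        raise RuntimeError(f"[stage: {stage}] {exc}") from exc
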