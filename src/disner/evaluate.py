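"""Mention-level and concept-level precision/recall/F1.

Mention level uses exact (doc_id, start, end) span matching, micro-averaged
over the corpus.  Concept level compares per-document sets of normalized
concept IDs ("-1" predictions are discarded first).
"""

from __future__ import annotations

from dataclasses import dataclass

from .corpus import Document


@dataclass(frozen=True)
class EvalResult:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn,
                "precision": self.precision, "recall": self.recall, "f1": self.f1}


def _pair_docs(predicted: list[Document], gold: list[Document]):
    pred_map = {d.doc_id: d for d in predicted}
    gold_map = {d.doc_id: d for d in gold}
    missing = sorted(set(pred_map) ^ set(gold_map))
    if missing:
        raise ValueError(f"unmatched doc_ids between corpora: {missing}")
    return [(pred_map[i], gold_map[i]) for i in sorted(gold_map)]


def evaluate_mentions(predicted: list[Document], gold: list[Document],
                      overlap: bool = False) -> EvalResult:
    """Micro-averaged exact-span mention matching (overlap=True relaxes to
    any-overlap matching; not the default convention)."""
    tp = fp = fn = 0
    for pred_doc, gold_doc in _pair_docs(predicted, gold):
        gold_spans = {(m.start, m.end) for m in gold_doc.mentions}
        pred_spans = {(m.start, m.end) for m in pred_doc.mentions}
        if not overlap:
            tp += len(gold_spans & pred_spans)
            fp += len(pred_spans - gold_spans)
            fn += len(gold_spans - pred_spans)
        else:
            matched_gold = set()
            for ps in pred_spans:
                hits = [gs for gs in gold_spans if ps[0] < gs[1] and gs[0] < ps[1]]
                if hits:
                    matched_gold.update(hits)
                    tp += 1
                else:
                    fp += 1
            fn += len(gold_spans - matched_gold)
    return EvalResult(tp=tp, fp=fp, fn=fn)


def evaluate_concepts(predicted: list[Document], gold: list[Document]) -> EvalResult:
    """Per-document concept-ID set comparison, counts pooled over docs."""
    tp = fp = fn = 0
    for pred_doc, gold_doc in _pair_docs(predicted, gold):
        pred_ids = {m.concept_id for m in pred_doc.mentions if m.concept_id != "-1"}
        gold_ids = {m.concept_id for m in gold_doc.mentions if m.concept_id != "-1"}
        tp += len(pred_ids & gold_ids)
        fp += len(pred_ids - gold_ids)
        fn += len(gold_ids - pred_ids)
    return EvalResult(tp=tp, fp=fp, fn=fn)
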