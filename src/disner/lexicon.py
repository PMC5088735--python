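"""Disease concept lexicon.

A lexicon maps concept identifiers to a preferred name plus synonym terms
(emulating a MeSH-derived disease dictionary with UMLS-style synonym
expansion).  It is consumed three ways: word-level dictionary flags and
greedy longest-term BIO matching (CRF features), abbreviation-definition
lookup (post-processing), and synonym-document TF-IDF indexing
(normalization).

On-disk format is a TSV with one concept per row:
``concept_id<TAB>preferred name<TAB>synonym|synonym|...``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .stem import porter_stem


def normalize_term(term: str, stem: bool = True) -> tuple[str, ...]:
    """Lowercase, split on non-alphanumerics, optionally Porter-stem."""
    words = []
    cur = []
    for ch in term:
        if ch.isalnum():
            cur.append(ch.lower())
        elif cur:
            words.append("".join(cur))
            cur = []
    if cur:
        words.append("".join(cur))
    if stem:
        words = [porter_stem(w) for w in words]
    return tuple(words)


@dataclass
class Lexicon:
    """concept_id -> (preferred name, synonyms), with derived match sets."""

    entries: dict[str, tuple[str, list[str]]] = field(default_factory=dict)
    stem_terms: bool = True

    def __post_init__(self) -> None:
        self._rebuild()

    def _rebuild(self) -> None:
        self.word_set: set[str] = set()
        self.term_set: set[tuple[str, ...]] = set()
        for cid, (name, synonyms) in self.entries.items():
            for term in [name, *synonyms]:
                norm = normalize_term(term, self.stem_terms)
                if not norm:
                    raise ValueError(f"concept {cid}: term {term!r} empty after normalization")
                self.term_set.add(norm)
                self.word_set.update(norm)
        self.max_term_len = max((len(t) for t in self.term_set), default=0)

    def add(self, concept_id: str, name: str, synonyms: list[str]) -> None:
        self.entries[concept_id] = (name, list(synonyms))
        self._rebuild()

    def terms(self, concept_id: str) -> list[str]:
        name, synonyms = self.entries[concept_id]
        return [name, *synonyms]

    def contains_word(self, word: str) -> bool:
        norm = normalize_term(word, self.stem_terms)
        return bool(norm) and all(w in self.word_set for w in norm)

    def contains_term(self, term: str) -> bool:
        return normalize_term(term, self.stem_terms) in self.term_set

    # --- TSV round trip --------------------------------------------------

    def to_tsv(self) -> str:
        lines = []
        for cid in sorted(self.entries):
            name, synonyms = self.entries[cid]
            lines.append(f"{cid}\t{name}\t{'|'.join(synonyms)}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str, stem_terms: bool = True) -> "Lexicon":
        entries: dict[str, tuple[str, list[str]]] = {}
        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"lexicon line {lineno}: expected >= 2 tab fields")
            cid, name = parts[0], parts[1]
            synonyms = [s for s in parts[2].split("|") if s] if len(parts) > 2 else []
            entries[cid] = (name, synonyms)
        return cls(entries=entries, stem_terms=stem_terms)
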