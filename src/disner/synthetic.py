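"""Seeded synthetic lexicons and corpora.

Generates disease-like concept lexicons (unique morpheme-composed names
with synonym variants and initial-letter abbreviations) and PubTator
corpora exhibiting the structures every pipeline stage consumes:
multi-word mentions with gold offsets and concept IDs, "long form (ABBR)"
abbreviation definitions followed by bare abbreviation mentions, surfaces
repeated within one abstract, distractor sentences, and "trap" modifier
words that occur both inside and outside entities.  Everything is
deterministic under the config seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .corpus import Document, Mention
from .lexicon import Lexicon

_ONSETS = ["card", "nephr", "hepat", "pulmon", "gastr", "neur", "derm",
           "ocul", "arthr", "myel", "oste", "enceph", "vascul", "bronch",
           "gloss", "phleb", "rhin", "splen", "thyr", "fibr", "lymph",
           "chondr", "cyst", "angi", "col"]
_SUFFIXES = ["itis", "osis", "oma", "opathy", "emia"]
_SUFFIX_VARIANT = {"itis": "itic inflammation", "osis": "otic degeneration",
                   "oma": "omatous growth", "opathy": "opathic disorder",
                   "emia": "emic imbalance"}
_MODIFIERS = ["acute", "chronic", "severe", "familial", "idiopathic",
              "recurrent", "congenital", "transient", "progressive",
              "refractory"]

_DISTRACTOR_SYLLABLES = ["ba", "co", "du", "fe", "gi", "ha", "ke", "lo",
                         "mi", "na", "po", "ru", "sa", "te", "vu"]

_TITLE_TEMPLATES = [
    "Study of {m} in hospitalized adults",
    "Clinical features of {m}",
    "Risk factors for {m} after surgery",
]
_TITLE_PLAIN = [
    "A randomized trial of standard supportive care",
    "Outcomes of an observational cohort study",
]
_MENTION_TEMPLATES = [
    "We observed {m} in twelve patients.",
    "Treatment with saline reduced {m} in most subjects.",
    "Several participants developed {m} after therapy.",
    "Clinicians documented {m} during follow up.",
    "The imaging findings suggested {m} in older adults.",
]
_TRAP_TEMPLATES = [
    "The {h} screening assay returned negative results.",
    "Serum {h} markers stayed within normal limits.",
    "Routine {h} panels were ordered for all participants.",
]
_DISTRACTOR_TEMPLATES = [
    "The control group received standard care.",
    "Baseline measurements were recorded daily.",
    "All participants provided informed consent.",
    "Samples were analyzed in a central laboratory.",
    "Patients entered the acute care unit on admission.",
    "The chronic administration of fluids continued overnight.",
    "Results were reviewed by two independent experts.",
]


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_docs: int = 100
    lexicon_size: int = 30
    synonyms_range: tuple[int, int] = (1, 3)
    abbrev_prob: float = 0.3
    repeat_prob: float = 0.4
    mention_density: float = 0.6
    trap_prob: float = 0.25
    distractor_vocab_size: int = 30
    sentences_range: tuple[int, int] = (4, 7)

    def __post_init__(self) -> None:
        for p in (self.abbrev_prob, self.repeat_prob, self.mention_density,
                  self.trap_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_docs < 0 or self.lexicon_size <= 0:
            raise ValueError("sizes must be positive")


@dataclass
class Concept:
    concept_id: str
    name: str
    synonyms: list[str]
    abbreviation: str | None


def _initials(name: str) -> str:
    return "".join(w[0] for w in name.split()).upper()


def make_concepts(config: GeneratorConfig) -> list[Concept]:
    """Concepts with unique heads, 2-3-word names, synonym variants and
    (where unique) an initial-letter abbreviation."""
    rng = random.Random(config.seed)
    heads = [o + s for o in _ONSETS for s in _SUFFIXES]
    rng.shuffle(heads)
    if config.lexicon_size > len(heads):
        raise ValueError(f"lexicon_size capped at {len(heads)}")
    seen_abbrevs: set[str] = set()
    seen_terms: set[str] = set()
    concepts = []
    for k in range(config.lexicon_size):
        head = heads[k]
        mods = rng.sample(_MODIFIERS, k=rng.choice([1, 1, 2]))
        name = " ".join(mods + [head])
        abbr = _initials(name)
        if abbr in seen_abbrevs:
            abbr = None
        else:
            seen_abbrevs.add(abbr)
        suffix = next(s for s in _SUFFIXES if head.endswith(s))
        variant = head[: -len(suffix)] + _SUFFIX_VARIANT[suffix]
        candidates = [head, variant, " ".join([head] + mods[:1])]
        lo, hi = config.synonyms_range
        n_syn = rng.randint(lo, min(hi, len(candidates)))
        synonyms = candidates[:n_syn]
        if abbr:
            synonyms.append(abbr)
        terms = [name] + synonyms
        assert not (set(t.lower() for t in terms) & seen_terms)
        seen_terms.update(t.lower() for t in terms)
        concepts.append(Concept(concept_id=f"T{k + 1:04d}", name=name,
                                synonyms=synonyms, abbreviation=abbr))
    return concepts


def make_lexicon(config: GeneratorConfig) -> Lexicon:
    concepts = make_concepts(config)
    return Lexicon({c.concept_id: (c.name, list(c.synonyms)) for c in concepts})


def _distractor_words(config: GeneratorConfig, rng: random.Random) -> list[str]:
    words = set()
    while len(words) < config.distractor_vocab_size:
        w = "".join(rng.choice(_DISTRACTOR_SYLLABLES)
                    for _ in range(rng.randint(2, 3)))
        words.add(w)
    return sorted(words)


class _DocBuilder:
    """Accumulates text pieces while tracking mention offsets."""

    def __init__(self) -> None:
        self.parts: list[str] = []
        self.length = 0
        self.mentions: list[tuple[int, int, str, str]] = []

    def add(self, text: str) -> None:
        self.parts.append(text)
        self.length += len(text)

    def add_mention(self, surface: str, concept_id: str) -> None:
        self.mentions.append((self.length, self.length + len(surface),
                              surface, concept_id))
        self.add(surface)

    @property
    def text(self) -> str:
        return "".join(self.parts)


def _fill(builder: _DocBuilder, template: str, surface: str | None = None,
          concept_id: str | None = None) -> None:
    if surface is None:
        builder.add(template)
        return
    before, after = template.split("{m}")
    builder.add(before)
    builder.add_mention(surface, concept_id)
    builder.add(after)


def generate_corpus(lexicon: Lexicon, config: GeneratorConfig) -> list[Document]:
    """Documents with gold mentions drawn from *lexicon*.

    With probability ``abbrev_prob`` a document introduces one concept as
    ``<long form> (<ABBR>)`` and mentions the bare abbreviation again
    later; with probability ``repeat_prob`` one surface recurs in at least
    two sentences.  ``mention_density`` controls how many abstract
    sentences carry a mention at all.
    """
    rng = random.Random(config.seed + 1)
    concepts = {cid: Concept(cid, name, syns,
                             next((s for s in syns if s.isupper() and " " not in s), None))
                for cid, (name, syns) in lexicon.entries.items()}
    cids = sorted(concepts)
    distractors = _distractor_words(config, rng)
    docs = []
    for d in range(config.n_docs):
        doc_concepts = rng.sample(cids, k=min(rng.randint(1, 3), len(cids)))
        b_title = _DocBuilder()
        primary = concepts[doc_concepts[0]]
        if rng.random() < 0.5:
            _fill(b_title, rng.choice(_TITLE_TEMPLATES), primary.name,
                  primary.concept_id)
        else:
            _fill(b_title, rng.choice(_TITLE_PLAIN))
        title = b_title.text
        title_mentions = b_title.mentions

        b = _DocBuilder()
        n_sent = rng.randint(*config.sentences_range)
        abbrev_concept = None
        if rng.random() < config.abbrev_prob:
            for cid in doc_concepts:
                if concepts[cid].abbreviation:
                    abbrev_concept = concepts[cid]
                    break
            else:
                with_abbr = [cid for cid in cids if concepts[cid].abbreviation]
                if with_abbr:
                    cid = rng.choice(with_abbr)
                    doc_concepts.append(cid)
                    abbrev_concept = concepts[cid]
        repeat_surface: tuple[str, str] | None = None
        sentences_with_mentions = 0
        for s in range(n_sent):
            if b.parts:
                b.add(" ")
            if abbrev_concept is not None and s == 0:
                c = abbrev_concept
                before, after = rng.choice(_MENTION_TEMPLATES).split("{m}")
                b.add(before)
                b.add_mention(c.name, c.concept_id)
                b.add(" (")
                b.add_mention(c.abbreviation, c.concept_id)
                b.add(")")
                b.add(after)
                sentences_with_mentions += 1
                continue
            if abbrev_concept is not None and s == n_sent - 1:
                _fill(b, rng.choice(_MENTION_TEMPLATES),
                      abbrev_concept.abbreviation, abbrev_concept.concept_id)
                sentences_with_mentions += 1
                continue
            if rng.random() < config.mention_density:
                if repeat_surface is None and rng.random() < config.repeat_prob:
                    c = concepts[rng.choice(doc_concepts)]
                    repeat_surface = (c.name, c.concept_id)
                if repeat_surface is not None and rng.random() < 0.7:
                    surface, cid = repeat_surface
                else:
                    c = concepts[rng.choice(doc_concepts)]
                    terms = [c.name] + [t for t in c.synonyms
                                        if not (t.isupper() and " " not in t)]
                    surface, cid = rng.choice(terms), c.concept_id
                _fill(b, rng.choice(_MENTION_TEMPLATES), surface, cid)
                sentences_with_mentions += 1
            else:
                # trap: a disease head-word in a non-entity context, drawn
                # from a concept absent from this document (keeps gold and
                # the propagation rule consistent)
                other = [cid for cid in cids if cid not in doc_concepts]
                if other and rng.random() < config.trap_prob:
                    c = concepts[rng.choice(other)]
                    head = min(c.synonyms + [c.name], key=lambda t: len(t.split()))
                    b.add(rng.choice(_TRAP_TEMPLATES).format(h=head))
                elif rng.random() < 0.5:
                    w1, w2 = rng.choice(distractors), rng.choice(distractors)
                    b.add(f"The {w1} {w2} remained stable throughout.")
                else:
                    b.add(rng.choice(_DISTRACTOR_TEMPLATES))
        abstract = b.text
        offset = len(title) + 1
        mentions = [Mention(s0, e0, surf, "Disease", cid)
                    for s0, e0, surf, cid in title_mentions]
        mentions += [Mention(s0 + offset, e0 + offset, surf, "Disease", cid)
                     for s0, e0, surf, cid in b.mentions]
        doc = Document(doc_id=str(10000 + d), title=title, abstract=abstract,
                       mentions=sorted(mentions, key=lambda m: (m.start, m.end)))
        doc.validate()
        docs.append(doc)
    return docs


def split_corpus(docs: list[Document], fractions: tuple[float, float, float],
                 seed: int = 0):
    """Disjoint, exhaustive, seed-deterministic (train, dev, test) split."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    rng = random.Random(seed)
    order = list(docs)
    rng.shuffle(order)
    n = len(order)
    n_train = int(round(fractions[0] * n))
    n_dev = int(round(fractions[1] * n))
    train = order[:n_train]
    dev = order[n_train:n_train + n_dev]
    test = order[n_train + n_dev:]
    return train, dev, test
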