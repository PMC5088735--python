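"""Rule-based recall boosters applied to base-tagger output.

Two monotone operations that only ever add mentions:

* repeated-entity propagation — a surface string tagged at least
  ``min_count`` times in one abstract is trusted enough to tag its
  remaining occurrences too;
* abbreviation resolution — Schwartz-Hearst detection of
  ``<definition> (<abbreviation>)`` patterns; when the definition is a
  known disease term (lexicon hit) or is itself tagged, every occurrence
  of the abbreviation becomes a mention.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from .corpus import Document, Mention
from .lexicon import Lexicon

logger = logging.getLogger("disner.postprocess")


def _occurrences(text: str, surface: str) -> list[tuple[int, int]]:
    """Case-insensitive occurrences of *surface* at token boundaries."""
    spans = []
    pattern = re.escape(surface)
    for m in re.finditer(pattern, text, re.IGNORECASE):
        s, e = m.start(), m.end()
        left_ok = s == 0 or not (text[s - 1].isalnum() and text[s].isalnum())
        right_ok = e == len(text) or not (text[e - 1].isalnum() and text[e].isalnum())
        if left_ok and right_ok:
            spans.append((s, e))
    return spans


def _overlaps(span: tuple[int, int], mentions: list[Mention]) -> bool:
    s, e = span
    return any(m.start < e and s < m.end for m in mentions)


def propagate_repeated_entities(doc: Document, mentions: list[Mention],
                                min_count: int = 2) -> list[Mention]:
    """Tag every occurrence of any surface already tagged >= min_count
    times in the document.  Mentions are only added, never removed."""
    text = doc.full_text
    by_surface: dict[str, list[Mention]] = {}
    for m in mentions:
        by_surface.setdefault(m.surface.lower(), []).append(m)

    out = list(mentions)
    for surface_lc, group in by_surface.items():
        if len(group) < min_count:
            continue
        template = group[0]
        for span in _occurrences(text, template.surface):
            if _overlaps(span, out):
                continue
            added = Mention(start=span[0], end=span[1], surface=text[span[0]:span[1]],
                            type=template.type, concept_id=template.concept_id)
            out.append(added)
            logger.info("doc %s: propagation added %r at [%d,%d)",
                        doc.doc_id, added.surface, added.start, added.end)
    out.sort(key=lambda m: (m.start, m.end))
    return out


@dataclass(frozen=True)
class AbbrevPair:
    """A '<definition> (<abbreviation>)' link with character offsets."""

    definition: str
    abbreviation: str
    definition_start: int
    definition_end: int
    abbreviation_start: int
    abbreviation_end: int


def _valid_short_form(a: str) -> bool:
    """Schwartz-Hearst short-form filter: 2-10 characters, at most two
    words, contains a letter, first character alphanumeric."""
    if not (2 <= len(a) <= 10):
        return False
    if len(a.split()) > 2:
        return False
    if not any(ch.isalpha() for ch in a):
        return False
    return a[0].isalnum()


def _find_best_long_form(long_form: str, short_form: str) -> int | None:
    """Right-to-left character alignment of the cited algorithm.

    Each short-form character must appear in the long form, scanning both
    right to left; the short form's first character must match the start
    of a word in the long form.  Returns the start index of the matched
    long form within *long_form*, or None.
    """
    s_idx = len(short_form) - 1
    l_idx = len(long_form) - 1
    while s_idx >= 0:
        c = short_form[s_idx].lower()
        if not c.isalnum():
            s_idx -= 1
            continue
        while l_idx >= 0 and (long_form[l_idx].lower() != c
                              or (s_idx == 0 and l_idx > 0 and long_form[l_idx - 1].isalnum())):
            l_idx -= 1
        if l_idx < 0:
            return None
        l_idx -= 1
        s_idx -= 1
    return l_idx + 1


def find_abbreviation_pairs(text: str) -> list[AbbrevPair]:
    """Detect '<definition> (<abbreviation>)' links in the text."""
    pairs = []
    for m in re.finditer(r"\(([^()]+)\)", text):
        candidate = m.group(1).strip()
        if not _valid_short_form(candidate):
            continue
        # candidate definition: the preceding words in the same sentence
        prefix = text[: m.start()].rstrip()
        sentence_start = max(prefix.rfind(". "), prefix.rfind("? "), prefix.rfind("! "))
        clause = prefix[sentence_start + 2:] if sentence_start >= 0 else prefix
        words = clause.split()
        if not words:
            continue
        max_words = min(len(candidate) + 5, len(candidate) * 2)
        window_words = words[-max_words:]
        window = " ".join(window_words)
        start_in_window = _find_best_long_form(window, candidate)
        if start_in_window is None:
            continue
        # snap to a word start within the window
        while start_in_window > 0 and window[start_in_window - 1] != " ":
            start_in_window -= 1
        definition = window[start_in_window:]
        if not definition or definition.lower() == candidate.lower():
            continue
        # definition must not be longer than the Schwartz-Hearst cap
        if len(definition.split()) > max_words:
            continue
        def_end = len(prefix)
        def_start = def_end - len(definition)
        if text[def_start:def_end] != definition:
            continue
        abbr_start = m.start(1) + (len(m.group(1)) - len(m.group(1).lstrip()))
        pairs.append(AbbrevPair(
            definition=definition, abbreviation=candidate,
            definition_start=def_start, definition_end=def_end,
            abbreviation_start=abbr_start, abbreviation_end=abbr_start + len(candidate)))
    return pairs


def resolve_abbreviations(doc: Document, mentions: list[Mention],
                          lexicon: Lexicon | None = None) -> list[Mention]:
    """Tag abbreviations whose definitions are known disease terms.

    For each detected pair, the definition qualifies if it is in the
    lexicon term set or if the span is already covered by a tagged
    mention; all occurrences of the abbreviation are then added."""
    text = doc.full_text
    out = list(mentions)
    for pair in find_abbreviation_pairs(text):
        in_lexicon = lexicon is not None and lexicon.contains_term(pair.definition)
        tagged = any(m.start <= pair.definition_start and m.end >= pair.definition_end
                     for m in mentions)
        # also accept a tagged mention that equals the definition surface
        tagged = tagged or any(m.surface.lower() == pair.definition.lower() for m in mentions)
        if not (in_lexicon or tagged):
            continue
        source = next((m for m in out
                       if m.start <= pair.definition_start and m.end >= pair.definition_end),
                      None)
        concept = source.concept_id if source else "-1"
        mtype = source.type if source else "Disease"
        for span in _occurrences(text, pair.abbreviation):
            if _overlaps(span, out):
                continue
            added = Mention(start=span[0], end=span[1], surface=text[span[0]:span[1]],
                            type=mtype, concept_id=concept)
            out.append(added)
            logger.info("doc %s: abbreviation %r resolved via %r, added at [%d,%d)",
                        doc.doc_id, pair.abbreviation, pair.definition,
                        added.start, added.end)
    out.sort(key=lambda m: (m.start, m.end))
    return out


def postprocess_mentions(doc: Document, mentions: list[Mention],
                         lexicon: Lexicon | None = None,
                         min_count: int = 2) -> list[Mention]:
    """Propagation followed by abbreviation resolution."""
    out = propagate_repeated_entities(doc, mentions, min_count=min_count)
    return resolve_abbreviations(doc, out, lexicon)
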