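"""PubTator corpus I/O and token/label plumbing.

A corpus is a list of :class:`Document` objects, each a PubMed-style
title + abstract with character-offset entity annotations.  Offsets are
0-based half-open and refer to ``title + " " + abstract`` (the BC5CDR
convention).  This module reads and writes the PubTator exchange format,
splits documents into sentences and offset-tracked tokens, and converts
between character-offset mentions and token-level BIO label sequences.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

logger = logging.getLogger("disner.corpus")

BIO_LABELS = ("B", "I", "O")


class PubTatorParseError(ValueError):
    """A line of PubTator input could not be parsed."""


class CorpusIntegrityError(ValueError):
    """A document violates an offset/surface invariant."""


@dataclass(frozen=True)
class Mention:
    """A contiguous entity annotation over the document's full text."""

    start: int
    end: int
    surface: str
    type: str = "Disease"
    concept_id: str = "-1"


@dataclass(frozen=True)
class Token:
    surface: str
    start: int
    end: int
    sentence_index: int = 0


@dataclass
class Document:
    doc_id: str
    title: str
    abstract: str
    mentions: list[Mention] = field(default_factory=list)

    @property
    def full_text(self) -> str:
        return self.title + " " + self.abstract

    def validate(self) -> None:
        text = self.full_text
        prev_end = -1
        for m in self.mentions:
            if not (0 <= m.start < m.end <= len(text)):
                raise CorpusIntegrityError(
                    f"doc {self.doc_id}: mention offsets [{m.start},{m.end}) "
                    f"outside text of length {len(text)}"
                )
            if text[m.start:m.end] != m.surface:
                raise CorpusIntegrityError(
                    f"doc {self.doc_id}: mention [{m.start},{m.end}) slices to "
                    f"{text[m.start:m.end]!r}, annotated surface {m.surface!r}"
                )
            if m.start < prev_end:
                raise CorpusIntegrityError(
                    f"doc {self.doc_id}: overlapping/unsorted mention at {m.start}"
                )
            prev_end = m.end


def parse_pubtator(stream) -> list[Document]:
    """Parse PubTator text (a string or line iterable) into Documents.

    Blocks are blank-line separated: a ``pmid|t|title`` line, a
    ``pmid|a|abstract`` line, then tab-separated mention lines
    ``pmid<TAB>start<TAB>end<TAB>surface<TAB>type<TAB>concept_id``.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = [ln.rstrip("\n") for ln in stream]

    docs: list[Document] = []
    cur: Document | None = None
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            if cur is not None:
                _finish(cur, docs)
                cur = None
            continue
        tm = re.match(r"^([^|\t]+)\|t\|(.*)$", line)
        am = re.match(r"^([^|\t]+)\|a\|(.*)$", line)
        if tm:
            if cur is not None:
                _finish(cur, docs)
            cur = Document(doc_id=tm.group(1), title=tm.group(2), abstract="")
            continue
        if am:
            if cur is None or cur.doc_id != am.group(1):
                raise PubTatorParseError(f"line {lineno}: abstract line without matching title")
            cur.abstract = am.group(2)
            continue
        parts = line.split("\t")
        if len(parts) < 6:
            raise PubTatorParseError(
                f"line {lineno}: expected 6 tab-separated fields, got {len(parts)}: {line!r}"
            )
        doc_id, start_s, end_s, surface, mtype, concept_id = parts[:6]
        if cur is None or cur.doc_id != doc_id:
            raise PubTatorParseError(f"line {lineno}: mention for unknown document {doc_id!r}")
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise PubTatorParseError(f"line {lineno}: non-integer offsets") from exc
        mention = Mention(start=start, end=end, surface=surface, type=mtype, concept_id=concept_id)
        text = cur.full_text
        if not (0 <= start < end <= len(text)) or text[start:end] != surface:
            raise CorpusIntegrityError(
                f"doc {doc_id}, line {lineno}: offsets [{start},{end}) slice to "
                f"{text[start:end]!r}, not {surface!r}"
            )
        cur.mentions.append(mention)
    if cur is not None:
        _finish(cur, docs)
    return docs


def _finish(doc: Document, docs: list[Document]) -> None:
    doc.mentions.sort(key=lambda m: (m.start, m.end))
    doc.validate()
    docs.append(doc)


def write_pubtator(docs: list[Document]) -> str:
    """Serialize Documents to PubTator text; inverse of :func:`parse_pubtator`."""
    blocks = []
    for doc in docs:
        doc.validate()
        lines = [f"{doc.doc_id}|t|{doc.title}", f"{doc.doc_id}|a|{doc.abstract}"]
        for m in doc.mentions:
            lines.append(
                f"{doc.doc_id}\t{m.start}\t{m.end}\t{m.surface}\t{m.type}\t{m.concept_id}"
            )
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + ("\n" if blocks else "")


# --- sentence splitting -------------------------------------------------

#: abbreviations after which a period never ends a sentence
_NON_TERMINAL = {"e.g", "i.e", "et al", "fig", "figs", "dr", "vs", "etc", "no", "ca", "approx"}

_BOUNDARY_RE = re.compile(r"[.?!]+(?=\s+[A-Z0-9(\[])")


def split_sentences(doc: Document, extra_abbreviations: set[str] | None = None) -> list[tuple[int, int]]:
    """Split a document's full text into sentence spans.

    Rule-based: a terminator followed by whitespace and an uppercase letter,
    digit or opening bracket ends a sentence, unless inside parentheses or
    after a known abbreviation.  The title is always its own sentence, and
    any boundary that would bisect a gold mention is suppressed.

    Returns (start, end) spans into ``doc.full_text``; their concatenation
    (with inter-span whitespace restored) reconstructs the text.
    """
    text = doc.full_text
    abbrevs = set(_NON_TERMINAL)
    if extra_abbreviations:
        abbrevs |= {a.lower().rstrip(".") for a in extra_abbreviations}

    boundaries = {len(doc.title)} if doc.abstract else set()
    depth = 0
    for i, ch in enumerate(text):
        if ch in "([":
            depth += 1
        elif ch in ")]":
            depth = max(0, depth - 1)
        elif ch in ".?!" and depth == 0:
            m = _BOUNDARY_RE.match(text, i)
            if m:
                word = re.search(r"(\S+)$", text[:i])
                if word and word.group(1).lower().rstrip(".") in abbrevs:
                    continue
                boundaries.add(m.end())

    # suppress boundaries that would bisect a mention
    for mention in doc.mentions:
        for b in [b for b in boundaries if mention.start < b < mention.end]:
            boundaries.discard(b)
            logger.info("doc %s: suppressed sentence boundary at %d inside mention %r",
                        doc.doc_id, b, mention.surface)

    spans: list[tuple[int, int]] = []
    start = 0
    for b in sorted(boundaries):
        seg = text[start:b]
        if seg.strip():
            s = start + (len(seg) - len(seg.lstrip()))
            e = start + len(seg.rstrip())
            spans.append((s, e))
        start = b
    seg = text[start:]
    if seg.strip():
        s = start + (len(seg) - len(seg.lstrip()))
        e = start + len(seg.rstrip())
        spans.append((s, e))
    return spans


# --- tokenization -------------------------------------------------------

_TOKEN_RE = re.compile(r"[A-Za-z]+|[0-9]+|[^\sA-Za-z0-9]")


def tokenize(span: tuple[int, int], text: str, sentence_index: int = 0) -> list[Token]:
    """Tokenize a sentence span: alphabetic runs, digit runs, and single
    punctuation characters (so hyphenated words split as word/-/word)."""
    start, end = span
    return [
        Token(surface=m.group(0), start=start + m.start(), end=start + m.end(),
              sentence_index=sentence_index)
        for m in _TOKEN_RE.finditer(text[start:end])
    ]


def tokenize_document(doc: Document) -> list[list[Token]]:
    """Sentence-split and tokenize a whole document."""
    return [tokenize(span, doc.full_text, i) for i, span in enumerate(split_sentences(doc))]


# --- BIO conversion -----------------------------------------------------

def mentions_to_bio(tokens: list[Token], mentions: list[Mention]) -> list[str]:
    """Project character-offset mentions onto token-level BIO labels.

    Mentions not aligned with token boundaries are snapped outward to the
    smallest covering token span (and logged), never dropped.
    """
    labels = ["O"] * len(tokens)
    for mention in mentions:
        idxs = [i for i, t in enumerate(tokens) if t.end > mention.start and t.start < mention.end]
        if not idxs:
            continue
        first, last = idxs[0], idxs[-1]
        if tokens[first].start != mention.start or tokens[last].end != mention.end:
            logger.info("mention %r [%d,%d) snapped to token span [%d,%d)",
                        mention.surface, mention.start, mention.end,
                        tokens[first].start, tokens[last].end)
        labels[first] = "B"
        for i in range(first + 1, last + 1):
            labels[i] = "I"
    return labels


def bio_to_mentions(tokens: list[Token], labels: list[str], text: str,
                    mention_type: str = "Disease") -> list[Mention]:
    """Decode BIO labels to mentions.  An orphan I (after O or at sequence
    start) is treated as B."""
    if len(tokens) != len(labels):
        raise ValueError(f"{len(tokens)} tokens vs {len(labels)} labels")
    mentions: list[Mention] = []
    i = 0
    while i < len(labels):
        if labels[i] in ("B", "I"):
            j = i + 1
            while j < len(labels) and labels[j] == "I":
                j += 1
            start, end = tokens[i].start, tokens[j - 1].end
            mentions.append(Mention(start=start, end=end, surface=text[start:end],
                                    type=mention_type))
            i = j
        else:
            i += 1
    return mentions


def repair_bio(labels: list[str]) -> list[str]:
    """Rewrite orphan I labels (after O or at start) as B."""
    out = list(labels)
    for i, lab in enumerate(out):
        if lab == "I" and (i == 0 or out[i - 1] == "O"):
            out[i] = "B"
    return out


def with_mentions(doc: Document, mentions: list[Mention]) -> Document:
    """Copy of *doc* with a replaced, sorted mention list."""
    new = Document(doc.doc_id, doc.title, doc.abstract,
                   sorted(mentions, key=lambda m: (m.start, m.end)))
    new.validate()
    return new


def document_bio(doc: Document) -> list[tuple[list[Token], list[str]]]:
    """Per-sentence (tokens, BIO labels) pairs for a gold document."""
    out = []
    for sent_tokens in tokenize_document(doc):
        out.append((sent_tokens, mentions_to_bio(sent_tokens, doc.mentions)))
    return out
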