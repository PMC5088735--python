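"""CRF feature extraction.

Seven per-token feature families — the word itself, POS tag, chunk tag,
word shape, character-class type, 1-4 character prefixes/suffixes, and two
dictionary look-up variants (a word-level Y/N flag and a greedy
longest-term BIO match) — each expanded over a small context window around
the token.  Feature values are strings; the CRF treats each
``name=value`` pair as a binary indicator.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .corpus import Token
from .lexicon import Lexicon, normalize_term

BOS = "__BOS__"
EOS = "__EOS__"


def word_shape(word: str) -> str:
    """Character-class transcription: uppercase->U, lowercase->L, digit->D,
    anything else->S.  'delirium' -> 'LLLLLLLL'."""
    if not word:
        raise ValueError("word_shape of empty word")
    out = []
    for ch in word:
        if ch.isupper():
            out.append("U")
        elif ch.islower():
            out.append("L")
        elif ch.isdigit():
            out.append("D")
        else:
            out.append("S")
    return "".join(out)


_TYPE_ORDER = (
    "AllDigit", "AllSymbol", "AllUpper", "AllLower", "AllLetter",
    "UpperAndDigit", "LetterAndDigit", "Mixed",
)


def word_type(word: str) -> str:
    """Coarse character-class category of a word (closed 8-value set)."""
    if not word:
        raise ValueError("word_type of empty word")
    has_upper = any(c.isupper() for c in word)
    has_lower = any(c.islower() for c in word)
    has_digit = any(c.isdigit() for c in word)
    has_symbol = any(not c.isalnum() for c in word)
    if has_digit and not (has_upper or has_lower or has_symbol):
        return "AllDigit"
    if has_symbol and not (has_upper or has_lower or has_digit):
        return "AllSymbol"
    if has_upper and not (has_lower or has_digit or has_symbol):
        return "AllUpper"
    if has_lower and not (has_upper or has_digit or has_symbol):
        return "AllLower"
    if (has_upper or has_lower) and not (has_digit or has_symbol):
        return "AllLetter"
    if has_upper and has_digit and not (has_lower or has_symbol):
        return "UpperAndDigit"
    if (has_upper or has_lower) and has_digit and not has_symbol:
        return "LetterAndDigit"
    return "Mixed"


def affixes(word: str, lengths: frozenset[int] | set[int] = frozenset({1, 2, 3, 4})):
    """Prefixes and suffixes of the requested lengths (only those that fit)."""
    if not lengths <= {1, 2, 3, 4}:
        raise ValueError("affix lengths must be within 1..4")
    out = []
    for ell in sorted(lengths):
        if ell <= len(word):
            out.append(("pre", ell, word[:ell]))
            out.append(("suf", ell, word[-ell:]))
    return out


def dict_flag(word: str, lexicon: Lexicon) -> str:
    """'Y' iff the (normalized) word occurs in any lexicon term."""
    return "Y" if lexicon.contains_word(word) else "N"


def dict_bio(tokens: list[Token] | list[str], lexicon: Lexicon) -> list[str]:
    """Greedy left-to-right longest dictionary-term match over the
    normalized token sequence; matched spans labelled B I*, others O."""
    surfaces = [t.surface if isinstance(t, Token) else t for t in tokens]
    norm = [normalize_term(s, lexicon.stem_terms) for s in surfaces]
    # a token normalizing to several words (e.g. "3-mg") joins with spaces
    flat = [" ".join(n) if n else "" for n in norm]
    labels = ["O"] * len(tokens)
    i = 0
    while i < len(tokens):
        best = 0
        for span in range(min(lexicon.max_term_len, len(tokens) - i), 0, -1):
            words = tuple(w for f in flat[i:i + span] for w in f.split(" ") if w)
            if words in lexicon.term_set:
                best = span
                break
        if best:
            labels[i] = "B"
            for j in range(i + 1, i + best):
                labels[j] = "I"
            i += best
        else:
            i += 1
    return labels


@dataclass
class FeatureConfig:
    """Window radii and toggles for the feature families.

    Radii default to 2 for word/POS/chunk/shape/type and 1 for the affix
    and dictionary families; all must lie in 1..3.
    """

    window_word: int = 2
    window_pos: int = 2
    window_chunk: int = 2
    window_shape: int = 2
    window_type: int = 2
    window_affix: int = 1
    window_dict: int = 1
    affix_lengths: frozenset = frozenset({1, 2, 3, 4})
    use_pos: bool = True
    use_chunk: bool = True
    use_dict_flag: bool = True
    use_dict_bio: bool = True

    def __post_init__(self) -> None:
        for name in ("window_word", "window_pos", "window_chunk", "window_shape",
                     "window_type", "window_affix", "window_dict"):
            if not 1 <= getattr(self, name) <= 3:
                raise ValueError(f"{name} must be in 1..3")
        self.affix_lengths = frozenset(self.affix_lengths)
        if not self.affix_lengths <= {1, 2, 3, 4}:
            raise ValueError("affix_lengths must be within 1..4")


def build_token_features(
    tokens: list[Token],
    pos_tags: list[str] | None,
    chunk_tags: list[str] | None,
    lexicon: Lexicon | None,
    config: FeatureConfig | None = None,
) -> list[dict[str, str]]:
    """One string-keyed feature map per token, with context windows.

    Keys encode the family and relative position, e.g. ``w[-1]``,
    ``shape[0]``, ``suf3[+1]``, ``dictB[0]``; positions past the sentence
    edge take BOS/EOS sentinel values.
    """
    cfg = config or FeatureConfig()
    T = len(tokens)
    if pos_tags is not None and len(pos_tags) != T:
        raise ValueError("POS tags misaligned with tokens")
    if chunk_tags is not None and len(chunk_tags) != T:
        raise ValueError("chunk tags misaligned with tokens")

    surfaces = [t.surface for t in tokens]
    shapes = [word_shape(s) for s in surfaces]
    types = [word_type(s) for s in surfaces]
    flags = [dict_flag(s, lexicon) for s in surfaces] if (lexicon and cfg.use_dict_flag) else None
    dbio = dict_bio(tokens, lexicon) if (lexicon and cfg.use_dict_bio) else None

    def window(values, radius):
        def at(i):
            if i < 0:
                return BOS
            if i >= T:
                return EOS
            return values[i]
        return at, radius

    columns: list[tuple[str, object, int]] = [("w", surfaces, cfg.window_word)]
    if pos_tags is not None and cfg.use_pos:
        columns.append(("pos", pos_tags, cfg.window_pos))
    if chunk_tags is not None and cfg.use_chunk:
        columns.append(("chk", chunk_tags, cfg.window_chunk))
    columns.append(("shape", shapes, cfg.window_shape))
    columns.append(("type", types, cfg.window_type))
    if flags is not None:
        columns.append(("dictA", flags, cfg.window_dict))
    if dbio is not None:
        columns.append(("dictB", dbio, cfg.window_dict))

    maps: list[dict[str, str]] = []
    for i in range(T):
        fmap: dict[str, str] = {}
        for name, values, radius in columns:
            at, _ = window(values, radius)
            for d in range(-radius, radius + 1):
                fmap[f"{name}[{d:+d}]".replace("+0", "0").replace("-0", "0")] = at(i + d)
        for d in range(-cfg.window_affix, cfg.window_affix + 1):
            j = i + d
            pos_key = f"[{d:+d}]".replace("+0", "0")
            if 0 <= j < T:
                for kind, ell, s in affixes(surfaces[j], cfg.affix_lengths):
                    fmap[f"{kind}{ell}{pos_key}"] = s
            else:
                fmap[f"afx{pos_key}"] = BOS if j < 0 else EOS
        maps.append(fmap)
    return maps


# --- bundled POS / chunk tagger ----------------------------------------

_POS_RULES: list[tuple[re.Pattern, str]] = [
    (re.compile(r"^[0-9]+$"), "CD"),
    (re.compile(r"^[^A-Za-z0-9]+$"), "PUNCT"),
    (re.compile(r"^(the|a|an|this|that|these|those)$", re.I), "DT"),
    (re.compile(r"^(in|of|on|with|for|to|from|by|at|after|during|under)$", re.I), "IN"),
    (re.compile(r"^(and|or|but)$", re.I), "CC"),
    (re.compile(r"^(is|are|was|were|be|been|has|have|had|did|does|do)$", re.I), "VB"),
    (re.compile(r".*(ed|ated)$", re.I), "VBD"),
    (re.compile(r".*ing$", re.I), "VBG"),
    (re.compile(r".*(ly)$", re.I), "RB"),
    (re.compile(r".*(ous|ic|al|ive|ary|able|acute|chronic|severe)$", re.I), "JJ"),
    (re.compile(r"^[A-Z]{2,}[0-9]*$"), "NNP"),
    (re.compile(r".*s$", re.I), "NNS"),
]


class SimpleTagger:
    """Rule-based POS tagger and NP chunker (pluggable stand-in interface).

    Any callable ``tokens -> (pos_tags, chunk_tags)`` can replace it in the
    pipeline; this implementation uses suffix/closed-class regex rules and a
    determiner-adjective-noun chunking pass.
    """

    TAGSET = ("CD", "PUNCT", "DT", "IN", "CC", "VB", "VBD", "VBG", "RB",
              "JJ", "NNP", "NNS", "NN")
    CHUNKSET = ("B-NP", "I-NP", "O")

    def __call__(self, tokens: list[Token] | list[str]) -> tuple[list[str], list[str]]:
        surfaces = [t.surface if isinstance(t, Token) else t for t in tokens]
        pos = []
        for s in surfaces:
            tag = "NN"
            for pat, t in _POS_RULES:
                if pat.match(s):
                    tag = t
                    break
            pos.append(tag)
        chunks = []
        in_np = False
        for tag in pos:
            if tag in ("DT", "JJ", "NN", "NNS", "NNP", "CD"):
                chunks.append("I-NP" if in_np else "B-NP")
                in_np = True
            else:
                chunks.append("O")
                in_np = False
        return pos, chunks
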