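"""Tokenization and numeric normalization shared by the extractors.

The negation-window logic counts *word* tokens: punctuation never counts
toward the window and windows stop at sentence boundaries (periods,
semicolons, newlines). Numeric tokens are normalized to floats with a
locale-tolerant rule that accepts both "." and "," decimal marks and strips
grouped thousands separators ("1.204,5" -> 1204.5).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import List, Optional

# A token is either a number (possibly with , / . separators) or a word
# (unicode letters/digits, internal hyphens kept out so "child-pugh"
# splits into two word tokens).
_TOKEN_RE = re.compile(r"\d+(?:[.,]\d+)*|[^\W\d_]+\d*", re.UNICODE)

_SENTENCE_BREAK_RE = re.compile(r"[.;:\n]")

_GROUPED_RE = re.compile(r"^\d{1,3}(?:[.,]\d{3})+$")


@dataclass(frozen=True)
class Token:
    text: str  # lowercased surface form
    start: int  # character offset in the source text
    end: int
    sentence: int  # index of the enclosing sentence
    value: Optional[float] = None  # normalized numeric value, if numeric

    @property
    def is_number(self) -> bool:
        return self.value is not None


def normalize_number(raw: str) -> Optional[float]:
    """Parse a numeric surface form, resolving decimal/thousands marks.

    Rules (applied in order):

    * both "." and "," present -> the last separator is the decimal mark,
      the other is a thousands separator ("1.204,5" -> 1204.5);
    * a single separator with groups of exactly three digits after a 1-3
      digit head is a thousands separator ("1.204" -> 1204.0);
    * otherwise a single separator is a decimal mark ("3,2" -> 3.2).
    """
    if not raw:
        return None
    has_dot = "." in raw
    has_comma = "," in raw
    try:
        if has_dot and has_comma:
            dec = "." if raw.rfind(".") > raw.rfind(",") else ","
            thou = "," if dec == "." else "."
            cleaned = raw.replace(thou, "").replace(dec, ".")
            return float(cleaned)
        if has_dot or has_comma:
            sep = "." if has_dot else ","
            if _GROUPED_RE.match(raw):
                return float(raw.replace(sep, ""))
            if raw.count(sep) > 1:  # malformed, e.g. "1.2.3"
                return None
            return float(raw.replace(sep, "."))
        return float(raw)
    except ValueError:
        return None


def tokenize(text: str) -> List[Token]:
    """Lowercased word/number tokens with source offsets and sentence ids.

    Tokens like ``b7`` (a Child-Pugh class-score compound) are kept as a
    single word token; the numeric extractor handles them separately.
    """
    # Sentence id for every character position.
    sent_id = 0
    boundaries = [m.start() for m in _SENTENCE_BREAK_RE.finditer(text)]
    tokens: List[Token] = []
    b_iter = iter(boundaries + [len(text) + 1])
    next_break = next(b_iter)
    for m in _TOKEN_RE.finditer(text):
        while m.start() > next_break:
            sent_id += 1
            next_break = next(b_iter)
        surface = m.group(0).lower()
        value = None
        if surface[0].isdigit():
            value = normalize_number(surface)
        tokens.append(
            Token(text=surface, start=m.start(), end=m.end(), sentence=sent_id, value=value)
        )
    return tokens


def split_paragraphs(text: str) -> List[str]:
    """Split text on blank-line boundaries, dropping empty paragraphs."""
    parts = re.split(r"\n\s*\n", text)
    return [p.strip() for p in parts if p.strip()]


_YEAR_RE = re.compile(r"\b(19\d{2}|20\d{2})\b")


def find_years(text: str) -> List[int]:
    """All plausible 4-digit years mentioned in a text."""
    return [int(m.group(1)) for m in _YEAR_RE.finditer(text)]
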