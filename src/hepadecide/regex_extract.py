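"""Deterministic pattern-based extraction of the 12 clinical targets.

Categorical concepts are detected by matching dictionary terms as contiguous
token sequences and inspecting a fixed window of word tokens on either side
of the match span for negation phrases (three words by default, never
crossing a sentence boundary). Numerical parameters take the numeric token
nearest to a keyword marker; the nodule diameter is resolved from the most
recent dated imaging section only, so stale measurements in older sections
are ignored.
"""

from __future__ import annotations

import re
from typing import List, Optional, Sequence, Tuple, Union

from .lexicon import DictionarySet, NumericSpec, TermDictionary
from .records import (
    ABSENT,
    NOT_REPORTED,
    PRESENT,
    ClinicalNote,
    StructuredRecord,
)
from .textproc import Token, find_years, split_paragraphs, tokenize

Number = Union[float, str]


def _find_spans(tokens: Sequence[Token], token_terms) -> List[Tuple[int, int]]:
    """All (start, end) token index spans matching any term, end exclusive."""
    spans = []
    texts = [t.text for t in tokens]
    n = len(texts)
    for term in token_terms:
        k = len(term)
        for i in range(n - k + 1):
            if tuple(texts[i : i + k]) == term:
                spans.append((i, i + k))
    return sorted(set(spans))


def _negated(tokens: Sequence[Token], span: Tuple[int, int], negators, window: int) -> bool:
    """Negation phrase within `window` word tokens of the span, same sentence."""
    start, end = span
    neg = set(negators)
    sent = tokens[start].sentence
    lo = max(0, start - window)
    for i in range(lo, start):
        if tokens[i].sentence == sent and tokens[i].text in neg:
            return True
    hi = min(len(tokens), end + window)
    for i in range(end, hi):
        if tokens[i].sentence == tokens[end - 1].sentence and tokens[i].text in neg:
            return True
    return False


def detect_concept(text: str, dictionary: TermDictionary) -> str:
    """Tri-state presence of one concept.

    ``not_reported`` when no term matches; ``absent`` when every mention is
    negated; ``present`` as soon as any mention is non-negated (clinical
    notes restate findings, so affirmation dominates).
    """
    tokens = tokenize(text)
    spans = _find_spans(tokens, dictionary.token_terms)
    if not spans:
        return NOT_REPORTED
    for span in spans:
        if not _negated(tokens, span, dictionary.negators, dictionary.window):
            return PRESENT
    return ABSENT


_CHILD_COMPOUND_RE = re.compile(
    r"child[\s\-]*pugh[\s\-]*(?:class[ae]?\s+)?([abc])\s*[-:]?\s*(\d{1,2})\b",
    re.IGNORECASE,
)


def extract_numeric(text: str, spec: NumericSpec) -> Number:
    """Numeric value nearest to a keyword marker, or ``not_reported``.

    Distance is counted in word tokens from the keyword match span within
    the same sentence, up to ``spec.max_gap``; ties prefer the value
    following the keyword. Child-Pugh class-score compounds ("B7") resolve
    to the score.
    """
    if spec.compound_class:
        m = _CHILD_COMPOUND_RE.search(text)
        if m:
            return _apply_domain(float(m.group(2)), spec)
    tokens = tokenize(text)
    spans = _find_spans(tokens, spec.token_keywords)
    candidates = []  # (distance, after_flag(0=after), position, value)
    for start, end in spans:
        sent = tokens[start].sentence
        for i, tok in enumerate(tokens):
            if not tok.is_number or tok.sentence != sent:
                continue
            if i >= end:
                dist, order = i - end + 1, 0
            elif i < start:
                dist, order = start - i, 1
            else:
                continue
            if dist <= spec.max_gap:
                candidates.append((dist, order, i, tok.value))
    if not candidates:
        return NOT_REPORTED
    candidates.sort()
    return _apply_domain(candidates[0][3], spec)


def _apply_domain(value: float, spec: NumericSpec) -> Number:
    if spec.domain is not None:
        lo, hi = spec.domain
        if not lo <= value <= hi:
            return NOT_REPORTED
    return float(value)


def _imaging_sections(text: str, dicts: DictionarySet) -> List[Tuple[int, str]]:
    """(year, paragraph) for paragraphs that look like dated imaging sections."""
    sections = []
    keywords = set(dicts.diameter.section_keywords)
    for para in split_paragraphs(text):
        years = find_years(para)
        if not years:
            continue
        para_tokens = {t.text for t in tokenize(para)}
        if para_tokens & keywords:
            sections.append((max(years), para))
    return sections


def extract_nodule_diameter(text: str, dicts: DictionarySet) -> Number:
    """Maximum dimensional value (mm) in the most recent imaging section.

    The section with the highest documented year wins (ties resolved by
    document position, latest first); centimetre values are normalized to
    millimetres. ``not_reported`` when there is no imaging section or no
    dimensional mention within it.
    """
    sections = _imaging_sections(text, dicts)
    if not sections:
        return NOT_REPORTED
    best_year = max(year for year, _ in sections)
    latest = [para for year, para in sections if year == best_year][-1]
    tokens = tokenize(latest)
    mm_units = set(dicts.diameter.mm_units)
    cm_units = set(dicts.diameter.cm_units)
    values = []
    for i, tok in enumerate(tokens[:-1]):
        if not tok.is_number:
            continue
        unit = tokens[i + 1].text
        if unit in mm_units:
            values.append(float(tok.value))
        elif unit in cm_units:
            values.append(float(tok.value) * 10.0)
    if not values:
        return NOT_REPORTED
    return max(values)


def regex_extract_all(
    note: Union[ClinicalNote, str], dicts: DictionarySet
) -> StructuredRecord:
    """One :class:`StructuredRecord` from a note, provenance ``regex``."""
    text = note.text if isinstance(note, ClinicalNote) else note
    record = StructuredRecord()
    for name, dictionary in dicts.concepts.items():
        record.set(name, detect_concept(text, dictionary), provenance="regex")
    for name, spec in dicts.numerics.items():
        record.set(name, extract_numeric(text, spec), provenance="regex")
    record.set(
        "max_nodule_diameter_mm", extract_nodule_diameter(text, dicts), provenance="regex"
    )
    record.validate()
    return record
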