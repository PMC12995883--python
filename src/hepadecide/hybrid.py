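"""LLM-primary extraction with per-field regex fallback.

The language model extracts first; any field it reports is kept verbatim
(regex is not consulted for it). For every field the model leaves
``not reported`` the regex extractor is triggered as a backup, and its value
— when it finds one — enters the record with provenance ``fallback_regex``.
A field ends up ``not_reported`` only when both extractors fail.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

from .lexicon import DictionarySet
from .llm import ExemplarPair, GenerationBackend, llm_extract, render_record_lines
from .records import ALL_FIELDS, NOT_REPORTED, ClinicalNote, StructuredRecord
from .regex_extract import regex_extract_all

logger = logging.getLogger(__name__)


def hybrid_extract(
    note: ClinicalNote,
    backend: GenerationBackend,
    dicts: DictionarySet,
    exemplars: Sequence[ExemplarPair],
    audit: bool = False,
) -> StructuredRecord:
    """Field-wise LLM -> regex fallback.

    With ``audit=True`` regex runs on every field and disagreements with
    reported LLM values are logged; the output record is unchanged.
    """
    record = llm_extract(note, backend, exemplars)
    missing = [f for f in ALL_FIELDS if record.get(f) == NOT_REPORTED]
    if missing or audit:
        regex_record = regex_extract_all(note, dicts)
        for name in missing:
            value = regex_record.get(name)
            if value != NOT_REPORTED:
                record.set(name, value, provenance="fallback_regex")
        if audit:
            for name in ALL_FIELDS:
                if name in missing:
                    continue
                llm_v, rx_v = record.get(name), regex_record.get(name)
                if rx_v != NOT_REPORTED and llm_v != rx_v:
                    logger.info(
                        "audit disagreement on %s/%s: llm=%r regex=%r",
                        note.case_id, name, llm_v, rx_v,
                    )
    return record


def render_structured_note(record: StructuredRecord) -> str:
    """Canonical fixed-order ``Field: value`` block for one record.

    Round-trips through :func:`hepadecide.llm.parse_extraction_output`;
    unreported fields are rendered explicitly as ``not reported``.
    """
    return render_record_lines(record)
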