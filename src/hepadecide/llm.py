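"""Generation-backend abstraction and LLM-based extraction.

Any object with a ``name`` and a ``generate(prompt, config) -> str`` method
can serve as a backend — a locally hosted model, an HTTP endpoint, or the
deterministic mocks below. The mocks make the whole pipeline testable
without model weights: the oracle mock answers extraction prompts by
applying the regex extractor to the report embedded in the prompt, and the
noisy mock degrades the oracle with seeded per-field drop/flip noise so
ablation deltas are measurable.
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Optional, Protocol, Sequence, runtime_checkable

import numpy as np

from .lexicon import DictionarySet, load_dictionaries
from .records import (
    ABSENT,
    ALL_FIELDS,
    CONCEPT_FIELDS,
    FIELD_LABELS,
    NOT_REPORTED,
    NUMERIC_FIELDS,
    PRESENT,
    ClinicalNote,
    StructuredRecord,
)
from .regex_extract import regex_extract_all
from .textproc import normalize_number

logger = logging.getLogger(__name__)

EXEMPLARS_PER_PROMPT = 10


class BackendError(RuntimeError):
    """A generation backend failed for one case."""


@dataclass(frozen=True)
class GenerationConfig:
    temperature: float
    max_tokens: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.max_tokens < 1:
            raise ValueError("max_tokens must be >= 1")


#: Deterministic settings used for the extraction task.
EXTRACTION_PROFILE = GenerationConfig(temperature=0.0, max_tokens=50)
#: Sampling settings used for the decision task.
DECISION_PROFILE = GenerationConfig(temperature=0.8, max_tokens=500)


@runtime_checkable
class GenerationBackend(Protocol):
    name: str

    def generate(self, prompt: str, config: GenerationConfig) -> str: ...


@dataclass(frozen=True)
class ExemplarPair:
    """One worked report -> extraction example for few-shot prompting."""

    input_note: str
    target_output: str


def render_record_lines(record: StructuredRecord) -> str:
    """Serialize a record as the canonical 12-line ``Field: value`` block."""
    lines = []
    for name in ALL_FIELDS:
        value = record.get(name)
        if value == NOT_REPORTED:
            text = "not reported"
        elif name in CONCEPT_FIELDS:
            text = value
        else:
            v = float(value)
            text = str(int(v)) if v == int(v) else f"{v:g}"
        lines.append(f"{FIELD_LABELS[name]}: {text}")
    return "\n".join(lines)


def _prompt_template() -> str:
    ref = resources.files("hepadecide").joinpath("data", "prompts", "extraction_en.txt")
    return ref.read_text(encoding="utf-8")


def build_extraction_prompt(
    note: ClinicalNote, exemplars: Sequence[ExemplarPair]
) -> str:
    """Deterministic extraction prompt: task spec, 10 worked examples,
    explicit instructions, then the target report."""
    if len(exemplars) != EXEMPLARS_PER_PROMPT:
        raise ValueError(
            f"extraction prompts require exactly {EXEMPLARS_PER_PROMPT} exemplars, "
            f"got {len(exemplars)}"
        )
    blocks = []
    for i, ex in enumerate(exemplars, start=1):
        blocks.append(
            f"--- Example {i} ---\nReport:\n{ex.input_note}\nExtraction:\n{ex.target_output}"
        )
    return _prompt_template().format(exemplars="\n\n".join(blocks), note=note.text)


_LABEL_INDEX = {
    re.sub(r"[^a-z0-9]", "", label.lower()): name for name, label in FIELD_LABELS.items()
}

_TRUE_WORDS = {"present", "yes", "positive", "presente", "presenti", "si"}
_FALSE_WORDS = {"absent", "no", "negative", "assente", "assenti"}
_NR_WORDS = {"not reported", "not_reported", "notreported", "nr", "non riportato", "unknown", ""}


def _parse_value(field_name: str, raw: str):
    value = raw.strip().lower().rstrip(".")
    if value in _NR_WORDS:
        return NOT_REPORTED
    if field_name in CONCEPT_FIELDS:
        if value in _TRUE_WORDS:
            return PRESENT
        if value in _FALSE_WORDS:
            return ABSENT
        return NOT_REPORTED
    m = re.search(r"\d+(?:[.,]\d+)*", value)
    if not m:
        return NOT_REPORTED
    number = normalize_number(m.group(0))
    if number is None or number < 0:
        return NOT_REPORTED
    return float(number)


def parse_extraction_output(raw: str) -> StructuredRecord:
    """Parse a line-keyed model answer into a record. Total: any field that
    is missing or malformed degrades to ``not_reported``."""
    record = StructuredRecord()
    parsed_any = False
    for line in (raw or "").splitlines():
        if ":" not in line:
            continue
        label, _, value = line.partition(":")
        key = re.sub(r"[^a-z0-9]", "", label.lower())
        name = _LABEL_INDEX.get(key)
        if name is None:
            continue
        parsed = _parse_value(name, value)
        record.set(name, parsed, provenance="llm")
        if parsed != NOT_REPORTED:
            parsed_any = True
    if not parsed_any:
        logger.warning("unparseable extraction output; all fields not_reported")
    try:
        record.validate()
    except ValueError:
        # out-of-domain numerics degrade to not_reported rather than raising
        for name in NUMERIC_FIELDS:
            v = record.get(name)
            if v != NOT_REPORTED and not (0 <= float(v) < float("inf")):
                record.set(name, NOT_REPORTED)
    return record


def llm_extract(
    note: ClinicalNote,
    backend: GenerationBackend,
    exemplars: Sequence[ExemplarPair],
    config: GenerationConfig = EXTRACTION_PROFILE,
) -> StructuredRecord:
    """Generate with the extraction profile and parse the answer."""
    prompt = build_extraction_prompt(note, exemplars)
    try:
        raw = backend.generate(prompt, config)
    except Exception as exc:  # noqa: BLE001 - error contract: annotate case
        raise BackendError(f"backend {backend.name!r} failed on case {note.case_id}") from exc
    return parse_extraction_output(raw)


# ---------------------------------------------------------------------------
# Mock backends
# ---------------------------------------------------------------------------

_REPORT_RE = re.compile(r"=== REPORT ===\n(.*?)\n=== EXTRACTION ===", re.DOTALL)


def _target_report(prompt: str) -> str:
    matches = _REPORT_RE.findall(prompt)
    if not matches:
        raise BackendError("prompt carries no report section")
    return matches[-1]


def stable_digest(*parts: str) -> int:
    """Deterministic 32-bit digest of strings (reproducible across runs)."""
    h = hashlib.sha256("\x1f".join(parts).encode("utf-8")).digest()
    return int.from_bytes(h[:4], "big")


class RegexOracleBackend:
    """Extraction mock that answers by running the regex extractor on the
    report embedded in the prompt (a report that is itself a structured
    12-field block is read off directly, as a language model would). With
    zero noise, LLM-based extraction on narrative notes is therefore exactly
    equivalent to regex extraction."""

    def __init__(self, dicts: Optional[DictionarySet] = None, name: str = "mock-oracle"):
        self.dicts = dicts or load_dictionaries("en")
        self.name = name

    def _extract(self, report: str) -> StructuredRecord:
        if "child-pugh score:" in report.lower():
            return parse_extraction_output(report)
        return regex_extract_all(report, self.dicts)

    def generate(self, prompt: str, config: GenerationConfig) -> str:
        return render_record_lines(self._extract(_target_report(prompt)))


class NoisyExtractionBackend:
    """Oracle extraction degraded by seeded per-field noise.

    Each field is independently dropped (answered "not reported") with
    probability ``drop_prob`` and, if kept, corrupted with probability
    ``flip_prob`` (concepts flip polarity; numerics are shifted). Noise is a
    pure function of (seed, prompt, field), so corpus runs are reproducible.
    """

    def __init__(
        self,
        dicts: Optional[DictionarySet] = None,
        drop_prob: float = 0.1,
        flip_prob: float = 0.0,
        seed: int = 0,
        name: str = "mock-noisy",
    ):
        self.oracle = RegexOracleBackend(dicts)
        self.drop_prob = drop_prob
        self.flip_prob = flip_prob
        self.seed = seed
        self.name = name

    def generate(self, prompt: str, config: GenerationConfig) -> str:
        record = self.oracle._extract(_target_report(prompt))
        for name in ALL_FIELDS:
            rng = np.random.default_rng(
                np.random.SeedSequence(
                    entropy=self.seed, spawn_key=(stable_digest(prompt, name),)
                )
            )
            if rng.random() < self.drop_prob:
                record.set(name, NOT_REPORTED)
                continue
            if rng.random() < self.flip_prob and record.get(name) != NOT_REPORTED:
                if name in CONCEPT_FIELDS:
                    flipped = ABSENT if record.get(name) == PRESENT else PRESENT
                    record.set(name, flipped, provenance="llm")
                else:
                    record.set(
                        name, float(record.get(name)) + float(rng.integers(1, 6)),
                        provenance="llm",
                    )
        return render_record_lines(record)


def make_exemplars(language: str = "en", seed: int = 12345) -> List[ExemplarPair]:
    """Ten deterministic synthetic report -> extraction pairs."""
    from .records import gold_to_structured
    from .synth import GeneratorConfig, generate_case

    config = GeneratorConfig(
        n_cases=EXEMPLARS_PER_PROMPT,
        missingness_rate=0.0,
        language=language,
        seed=seed,
    )
    pairs = []
    for i in range(EXEMPLARS_PER_PROMPT):
        bundle = generate_case(config, i)
        pairs.append(
            ExemplarPair(
                input_note=bundle.note.text,
                target_output=render_record_lines(gold_to_structured(bundle.gold)),
            )
        )
    return pairs
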