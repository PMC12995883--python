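"""Decision prompts under the six ablation configurations, and mocks.

The ablation grid crosses a prompting strategy (zero-shot, few-shot with 10
example cases, few-shot plus retrieval-augmented evidence) with an input
form (the raw narrative note vs. the structured 12-field block), yielding
six experimental configurations. Each (case, backend, configuration) cell
produces one :class:`~hepadecide.records.DecisionTriple`.
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .hybrid import render_structured_note
from .lexicon import DictionarySet, load_dictionaries
from .llm import DECISION_PROFILE, GenerationConfig, stable_digest
from .records import (
    COMPLEXITY_LEVELS,
    MDT_LEVELS,
    TREATMENTS,
    UNPARSEABLE,
    ClinicalNote,
    DecisionTriple,
    GoldRecord,
    StructuredRecord,
    gold_to_structured,
)
from .regex_extract import regex_extract_all
from .retrieval import RetrievalResult, VectorIndex
from .rules import decide_from_record
from .synth import ConfigurationError

logger = logging.getLogger(__name__)

PROMPTINGS = ("zero_shot", "few_shot", "few_shot_rag")
INPUT_FORMS = ("unstructured", "structured")

_CODE = {"zs": "zero_shot", "fs": "few_shot", "fsrag": "few_shot_rag",
         "raw": "unstructured", "structured": "structured"}


@dataclass(frozen=True)
class ConfigurationId:
    prompting: str
    input_form: str

    def __post_init__(self) -> None:
        if self.prompting not in PROMPTINGS or self.input_form not in INPUT_FORMS:
            raise ConfigurationError(
                f"invalid configuration: {self.prompting}/{self.input_form}"
            )

    @classmethod
    def from_code(cls, code: str) -> "ConfigurationId":
        """Parse a short code such as ``fsrag x structured`` or ``zs-raw``."""
        parts = [p for p in re.split(r"[x\-/\s]+", code.strip().lower()) if p]
        if len(parts) != 2 or parts[0] not in _CODE or parts[1] not in _CODE:
            raise ConfigurationError(f"cannot parse configuration code {code!r}")
        return cls(prompting=_CODE[parts[0]], input_form=_CODE[parts[1]])

    def __str__(self) -> str:
        return f"{self.prompting}/{self.input_form}"


ALL_CONFIGURATIONS = tuple(
    ConfigurationId(p, f) for p in PROMPTINGS for f in INPUT_FORMS
)

CorpusPair = Tuple[ClinicalNote, GoldRecord]


def case_input_text(
    note: ClinicalNote,
    gold: GoldRecord,
    input_form: str,
    structured_records: Optional[Dict[str, StructuredRecord]] = None,
) -> str:
    """The case representation fed to the decision prompt.

    Structured inputs default to the gold-derived 12-field block (isolating
    decision generation from extraction errors); pass ``structured_records``
    keyed by case id to use extracted records instead.
    """
    if input_form == "unstructured":
        return note.text
    if structured_records is not None and gold.case_id in structured_records:
        record = structured_records[gold.case_id]
    else:
        record = gold_to_structured(gold)
    return render_structured_note(record)


def select_fewshot_cases(
    corpus: Sequence[CorpusPair],
    input_form: str,
    n: int = 10,
    seed: int = 0,
    structured_records: Optional[Dict[str, StructuredRecord]] = None,
) -> Tuple[List[Tuple[str, DecisionTriple]], List[CorpusPair]]:
    """Sample ``n`` exemplar cases without replacement.

    Returns ``(exemplars, evaluation_corpus)``: the sampled
    (case input, reference decision) pairs in the requested input form, and
    the remaining cases. Raises when no evaluation case would remain.
    """
    if len(corpus) <= n:
        raise ConfigurationError(
            f"corpus of {len(corpus)} cases cannot supply {n} exemplars "
            "and a non-empty evaluation set"
        )
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(97,)))
    chosen = set(rng.choice(len(corpus), size=n, replace=False).tolist())
    exemplars = [
        (
            case_input_text(note, gold, input_form, structured_records),
            gold.reference_decision,
        )
        for i, (note, gold) in enumerate(corpus)
        if i in chosen
    ]
    remaining = [pair for i, pair in enumerate(corpus) if i not in chosen]
    return exemplars, remaining


_LABELS = {"treatment": "Treatment", "complexity": "Complexity", "mdt": "MDT"}


def format_decision(triple: DecisionTriple) -> str:
    return (
        f"Treatment: {triple.treatment.replace('_', ' ')}\n"
        f"Complexity: {triple.complexity}\n"
        f"MDT: {triple.mdt}"
    )


def _decision_template() -> str:
    ref = resources.files("hepadecide").joinpath("data", "prompts", "decision_en.txt")
    return ref.read_text(encoding="utf-8")


def build_decision_prompt(
    case_input: str,
    cfg: ConfigurationId,
    exemplars: Optional[Sequence[Tuple[str, DecisionTriple]]] = None,
    retrieved: Optional[Sequence[RetrievalResult]] = None,
) -> str:
    """Deterministic decision prompt for one configuration.

    Zero-shot prompts contain only the task specification and output schema;
    few-shot prompts append the 10 example pairs; RAG prompts additionally
    prepend the retrieved evidence chunks with source labels.
    """
    if cfg.prompting == "zero_shot":
        if exemplars:
            raise ConfigurationError("zero-shot prompts take no exemplars")
        examples = ""
    else:
        if not exemplars:
            raise ConfigurationError(f"{cfg} requires few-shot exemplars")
        blocks = []
        for i, (text, triple) in enumerate(exemplars, start=1):
            blocks.append(
                f"--- Example {i} ---\nCase:\n{text}\nDecision:\n{format_decision(triple)}"
            )
        examples = "=== EXAMPLES ===\n" + "\n\n".join(blocks) + "\n\n"
    if cfg.prompting == "few_shot_rag":
        if not retrieved:
            raise ConfigurationError("few_shot_rag requires retrieved evidence chunks")
        lines = [
            f"[{r.chunk.doc_id} #{r.chunk.chunk_index}] {r.chunk.text}"
            for r in retrieved
        ]
        evidence = "=== EVIDENCE ===\n" + "\n\n".join(lines) + "\n\n"
    else:
        if retrieved:
            raise ConfigurationError(f"{cfg} takes no retrieved chunks")
        evidence = ""
    return _decision_template().format(
        evidence=evidence, examples=examples, case=case_input
    )


# ---------------------------------------------------------------------------
# Output parsing
# ---------------------------------------------------------------------------

#: Free-text variants mapped to canonical treatment categories. Longer
#: patterns are matched first so e.g. "transarterial chemoembolization"
#: resolves before "ablation"-like substrings could.
TREATMENT_SYNONYMS: List[Tuple[str, str]] = [
    ("liver transplantation", "liver_transplantation"),
    ("transplantation", "liver_transplantation"),
    ("transplant", "liver_transplantation"),
    ("trapianto", "liver_transplantation"),
    ("surgical resection", "surgical_resection"),
    ("resection", "surgical_resection"),
    ("resezione", "surgical_resection"),
    ("hepatectomy", "surgical_resection"),
    ("epatectomia", "surgical_resection"),
    ("chemoembolization", "transarterial_treatment"),
    ("chemioembolizzazione", "transarterial_treatment"),
    ("radioembolization", "transarterial_treatment"),
    ("transarterial", "transarterial_treatment"),
    ("transarterioso", "transarterial_treatment"),
    ("tace", "transarterial_treatment"),
    ("tare", "transarterial_treatment"),
    ("thermoablation", "ablation"),
    ("radiofrequency", "ablation"),
    ("termoablazione", "ablation"),
    ("ablation", "ablation"),
    ("ablazione", "ablation"),
    ("rfa", "ablation"),
    ("systemic therapy", "systemic_therapy"),
    ("terapia sistemica", "systemic_therapy"),
    ("systemic", "systemic_therapy"),
    ("sorafenib", "systemic_therapy"),
    ("lenvatinib", "systemic_therapy"),
    ("atezolizumab", "systemic_therapy"),
    ("immunotherapy", "systemic_therapy"),
    ("best supportive care", "best_supportive_care"),
    ("supportive care", "best_supportive_care"),
    ("terapia di supporto", "best_supportive_care"),
    ("bsc", "best_supportive_care"),
    ("follow-up continuation", "follow_up_continuation"),
    ("follow up continuation", "follow_up_continuation"),
    ("follow-up", "follow_up_continuation"),
    ("follow up", "follow_up_continuation"),
    ("surveillance", "follow_up_continuation"),
    ("sorveglianza", "follow_up_continuation"),
    ("observation", "follow_up_continuation"),
]

COMPLEXITY_SYNONYMS: List[Tuple[str, str]] = [
    ("low", "low"), ("bassa", "low"),
    ("moderate", "moderate"), ("moderata", "moderate"), ("intermediate", "moderate"),
    ("intermedia", "moderate"),
    ("high", "high"), ("alta", "high"), ("elevata", "high"),
]


def _map_treatment(text: str) -> str:
    t = text.lower().replace("_", " ")
    for pattern, canonical in TREATMENT_SYNONYMS:
        if pattern in t:
            return canonical
    return UNPARSEABLE


def _map_complexity(text: str) -> str:
    t = text.lower()
    for pattern, canonical in COMPLEXITY_SYNONYMS:
        if re.search(rf"\b{pattern}\b", t):
            return canonical
    return UNPARSEABLE


def _map_mdt(text: str) -> str:
    t = text.lower()
    if re.search(r"\b(yes|si|sì|recommended|indicated)\b", t):
        return "yes"
    if re.search(r"\b(no|not)\b", t):
        return "no"
    return UNPARSEABLE


def parse_decision_output(raw: str) -> DecisionTriple:
    """Total parser: labeled lines first, free-text synonym scan as backup;
    anything unmappable becomes the ``unparseable`` sentinel (always scored
    as incorrect)."""
    raw = raw or ""
    fields = {"treatment": UNPARSEABLE, "complexity": UNPARSEABLE, "mdt": UNPARSEABLE}
    mappers = {"treatment": _map_treatment, "complexity": _map_complexity, "mdt": _map_mdt}
    labels = {
        "treatment": ("treatment", "trattamento", "allocation"),
        "complexity": ("complexity", "complessita", "complessità"),
        "mdt": ("mdt", "multidisciplinary", "multidisciplinare"),
    }
    # labeled segments may be newline- or slash-separated
    for line in re.split(r"[\n/;]", raw):
        if ":" not in line:
            continue
        label, _, value = line.partition(":")
        key = label.strip().lower()
        for field_name, variants in labels.items():
            if any(v in key for v in variants):
                mapped = mappers[field_name](value)
                if mapped != UNPARSEABLE:
                    fields[field_name] = mapped
    if all(v == UNPARSEABLE for v in fields.values()) and raw.strip():
        # free-prose answer: scan the whole text
        fields["treatment"] = _map_treatment(raw)
        fields["complexity"] = _map_complexity(raw)
        fields["mdt"] = UNPARSEABLE  # too ambiguous without a label
    return DecisionTriple(**fields)


# ---------------------------------------------------------------------------
# Mock decision backends
# ---------------------------------------------------------------------------

_TARGET_RE = re.compile(r"=== TARGET CASE ===\n(.*?)\n=== DECISION ===", re.DOTALL)


def _target_case(prompt: str) -> str:
    m = _TARGET_RE.findall(prompt)
    if not m:
        raise ConfigurationError("prompt carries no target case section")
    return m[-1]


def _looks_structured(case_text: str) -> bool:
    return "child-pugh score:" in case_text.lower()


class DecisionOracleBackend:
    """Decision mock that applies the reference rule table to the case
    embedded in the prompt (parsing the structured block directly, or
    regex-extracting a raw note first)."""

    def __init__(self, dicts: Optional[DictionarySet] = None, name: str = "mock-oracle"):
        self.dicts = dicts or load_dictionaries("en")
        self.name = name

    def _record(self, case_text: str) -> StructuredRecord:
        from .llm import parse_extraction_output

        if _looks_structured(case_text):
            return parse_extraction_output(case_text)
        return regex_extract_all(case_text, self.dicts)

    def generate(self, prompt: str, config: GenerationConfig) -> str:
        triple = decide_from_record(self._record(_target_case(prompt)))
        return format_decision(triple)


#: Per-configuration corruption probabilities for the noisy decision mock.
#: Structured input is configured to be easier than unstructured at every
#: prompting level, and each added context component helps.
DEFAULT_DECISION_ERROR_RATES: Dict[Tuple[str, str], float] = {
    ("zero_shot", "unstructured"): 0.72,
    ("zero_shot", "structured"): 0.62,
    ("few_shot", "unstructured"): 0.58,
    ("few_shot", "structured"): 0.50,
    ("few_shot_rag", "unstructured"): 0.42,
    ("few_shot_rag", "structured"): 0.20,
}


class NoisyDecisionBackend(DecisionOracleBackend):
    """Oracle decisions corrupted with a per-configuration flip probability.

    The backend sees only the prompt, so it infers the configuration from
    the prompt structure (evidence block -> RAG, example blocks -> few-shot,
    12-field case block -> structured). Each of the three decisions is
    independently replaced by a random different label with the configured
    probability; noise is a pure function of (seed, prompt)."""

    def __init__(
        self,
        dicts: Optional[DictionarySet] = None,
        error_rates: Optional[Dict[Tuple[str, str], float]] = None,
        flip_prob: Optional[float] = None,
        seed: int = 0,
        name: str = "mock-noisy",
    ):
        super().__init__(dicts, name=name)
        if flip_prob is not None:
            error_rates = {(p, f): flip_prob for p in PROMPTINGS for f in INPUT_FORMS}
        self.error_rates = dict(error_rates or DEFAULT_DECISION_ERROR_RATES)
        self.seed = seed

    @staticmethod
    def _infer_configuration(prompt: str) -> Tuple[str, str]:
        if "=== EVIDENCE ===" in prompt:
            prompting = "few_shot_rag"
        elif "=== EXAMPLES ===" in prompt:
            prompting = "few_shot"
        else:
            prompting = "zero_shot"
        form = "structured" if _looks_structured(_target_case(prompt)) else "unstructured"
        return prompting, form

    def generate(self, prompt: str, config: GenerationConfig) -> str:
        triple = decide_from_record(self._record(_target_case(prompt)))
        rate = self.error_rates[self._infer_configuration(prompt)]
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stable_digest(prompt),))
        )
        values = {"treatment": triple.treatment, "complexity": triple.complexity,
                  "mdt": triple.mdt}
        domains = {"treatment": TREATMENTS, "complexity": COMPLEXITY_LEVELS,
                   "mdt": MDT_LEVELS}
        for task, value in values.items():
            if rng.random() < rate:
                others = [v for v in domains[task] if v != value]
                values[task] = str(others[int(rng.integers(0, len(others)))])
        return format_decision(DecisionTriple(**values))


# ---------------------------------------------------------------------------
# Ablation runner
# ---------------------------------------------------------------------------


def run_ablation(
    corpus: Sequence[CorpusPair],
    backends: Sequence,
    configurations: Sequence[ConfigurationId] = ALL_CONFIGURATIONS,
    index: Optional[VectorIndex] = None,
    exemplar_corpus: Optional[Sequence[CorpusPair]] = None,
    n_fewshot: int = 10,
    seed: int = 0,
    k_per_doc: int = 5,
    structured_records: Optional[Dict[str, StructuredRecord]] = None,
    generation_config: GenerationConfig = DECISION_PROFILE,
) -> List[dict]:
    """One decision per (case, backend, configuration), with provenance.

    Few-shot exemplars come from ``exemplar_corpus`` when given; otherwise
    they are sampled from ``corpus`` and the sampled cases are excluded from
    evaluation in *all* configurations. Per-case backend failures are logged
    as error rows and the run continues.
    """
    if not backends or not configurations:
        raise ConfigurationError("need at least one backend and one configuration")
    needs_rag = any(c.prompting == "few_shot_rag" for c in configurations)
    if needs_rag and index is None:
        raise ConfigurationError("few_shot_rag configurations require a vector index")

    if exemplar_corpus is not None:
        eval_corpus = list(corpus)
        exemplar_source = list(exemplar_corpus)
    else:
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(97,)))
        if len(corpus) <= n_fewshot:
            raise ConfigurationError(
                f"corpus of {len(corpus)} cases cannot supply {n_fewshot} exemplars "
                "and a non-empty evaluation set"
            )
        chosen = set(rng.choice(len(corpus), size=n_fewshot, replace=False).tolist())
        exemplar_source = [pair for i, pair in enumerate(corpus) if i in chosen]
        eval_corpus = [pair for i, pair in enumerate(corpus) if i not in chosen]

    exemplars_by_form = {}
    for form in INPUT_FORMS:
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(11,)))
        idx = rng.choice(len(exemplar_source), size=min(n_fewshot, len(exemplar_source)),
                         replace=False)
        exemplars_by_form[form] = [
            (
                case_input_text(*exemplar_source[i], form, structured_records),
                exemplar_source[i][1].reference_decision,
            )
            for i in sorted(idx.tolist())
        ]

    rows: List[dict] = []
    for note, gold in eval_corpus:
        inputs = {
            form: case_input_text(note, gold, form, structured_records)
            for form in INPUT_FORMS
        }
        retrieved = {
            form: index.retrieve(inputs[form], k_per_doc=k_per_doc) if needs_rag else None
            for form in INPUT_FORMS
        }
        for cfg in configurations:
            prompt = build_decision_prompt(
                inputs[cfg.input_form],
                cfg,
                exemplars=exemplars_by_form[cfg.input_form]
                if cfg.prompting != "zero_shot"
                else None,
                retrieved=retrieved[cfg.input_form]
                if cfg.prompting == "few_shot_rag"
                else None,
            )
            digest = hashlib.sha256(prompt.encode("utf-8")).hexdigest()
            for backend in backends:
                row = {
                    "case_id": gold.case_id,
                    "backend": backend.name,
                    "prompting": cfg.prompting,
                    "input_form": cfg.input_form,
                    "prompt_sha256": digest,
                    "seed": seed,
                }
                try:
                    raw = backend.generate(prompt, generation_config)
                    triple = parse_decision_output(raw)
                    row.update(triple.as_dict())
                except Exception as exc:  # noqa: BLE001 - per-case error contract
                    logger.warning("backend %s failed on %s: %s",
                                   backend.name, gold.case_id, exc)
                    row.update(
                        treatment=UNPARSEABLE, complexity=UNPARSEABLE, mdt=UNPARSEABLE,
                        error=str(exc),
                    )
                rows.append(row)
    return rows
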