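"""Synthetic clinical-note corpus with known gold labels.

Every downstream stage (regex extraction, LLM prompting, decision support,
evaluation) is exercised against this generator, so each case carries a
complete :class:`~hepadecide.records.GoldRecord` plus rendering bookkeeping
(which fields were actually written into the note, which concepts were
negated) that the evaluation stage can use as an oracle.

Profiles are drawn *conditionally*: a treatment category and a complexity
grade are sampled from the configured cohort marginals, and a clinical
profile consistent with both is then constructed and verified against the
reference rule table. Free findings not pinned down by the category
(comorbidities, varices, previous treatment, ...) are negative with
probability ``negation_rate`` — negative findings are rendered as negated
mentions, which is what the negation-window extractor has to handle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from .records import (
    ALL_FIELDS,
    CONCEPT_FIELDS,
    ClinicalNote,
    DecisionTriple,
    GoldRecord,
    child_pugh_class_from_score,
)
from .rules import assign_reference_decision

#: Treatment mix of the emulated cohort (489 decision points).
DEFAULT_TREATMENT_MARGINALS = {
    "liver_transplantation": 0.041,
    "surgical_resection": 0.084,
    "ablation": 0.086,
    "transarterial_treatment": 0.100,
    "systemic_therapy": 0.309,
    "best_supportive_care": 0.194,
    "follow_up_continuation": 0.186,
}

#: Complexity mix of the emulated cohort (low / moderate / high).
DEFAULT_COMPLEXITY_MARGINALS = {"low": 0.231, "moderate": 0.556, "high": 0.213}


class ConfigurationError(ValueError):
    """Invalid generator or pipeline configuration."""


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic cohort.

    Defaults emulate the study cohort: mean age 71.2 +/- 10.6 years, 73.3%
    male, and the treatment/complexity mix above. ``negation_rate`` is the
    probability that a free binary finding is negative (hence expressed
    through a negation phrase); ``missingness_rate`` is the per-field
    probability that a parameter is omitted from the note text.
    """

    n_cases: int = 489
    marginals: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TREATMENT_MARGINALS)
    )
    complexity_marginals: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPLEXITY_MARGINALS)
    )
    mean_age: float = 71.2
    sd_age: float = 10.6
    male_fraction: float = 0.733
    negation_rate: float = 0.3
    missingness_rate: float = 0.1
    n_imaging_sections_range: Tuple[int, int] = (1, 3)
    language: str = "en"
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 1:
            raise ConfigurationError("n_cases must be >= 1")
        for name, m in (
            ("marginals", self.marginals),
            ("complexity_marginals", self.complexity_marginals),
        ):
            total = sum(m.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} must sum to 1 (got {total!r})")
            if any(p < 0 for p in m.values()):
                raise ConfigurationError(f"{name} must be non-negative")
        for name in ("negation_rate", "missingness_rate", "male_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1] (got {v})")
        lo, hi = self.n_imaging_sections_range
        if not (1 <= lo <= hi):
            raise ConfigurationError("n_imaging_sections_range must be a valid interval >= 1")
        if self.language not in ("en", "it"):
            raise ConfigurationError(f"unknown language template set: {self.language!r}")


@dataclass
class RenderInfo:
    """Bookkeeping of what :func:`render_note` actually wrote."""

    case_id: str
    rendered_fields: set
    negated_concepts: set
    decimal_style: str  # "dot" | "comma"
    imaging_years: List[int]
    decoy_diameters: List[float]


@dataclass
class CaseBundle:
    note: ClinicalNote
    gold: GoldRecord
    render: RenderInfo


def _case_rng(seed: int, case_index: int, stream: int = 0) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(case_index, stream))
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# Profile construction
# ---------------------------------------------------------------------------

_BAND_BOUNDS = {"low": (0, 1), "moderate": (2, 3), "high": (4, 99)}


def _draw_structural(
    category: str, rng: np.random.Generator, negation_rate: float
) -> Tuple[dict, List[str]]:
    """Draw category-consistent structural attributes and free findings.

    Returns the profile plus the list of *flexible* concepts: findings whose
    value was drawn freely (rather than dictated by the treatment category)
    and may be flipped to steer the complexity grade without changing the
    treatment allocation.
    """

    def free() -> bool:
        return bool(rng.random() >= negation_rate)

    p = {
        "vascular_invasion": False,
        "metastatic_disease": False,
        "esophageal_varices": False,
        "severe_comorbidities": free(),
        "previous_hcc_treatment": free(),
        "complete_response_last_treatment": False,
    }
    flex = ["severe_comorbidities"]
    if category == "follow_up_continuation":
        p.update(
            previous_hcc_treatment=True,
            complete_response_last_treatment=True,
            esophageal_varices=free(),
            ecog_ps=int(rng.integers(0, 3)),
            child_pugh_score=int(rng.integers(5, 10)),
            n_nodules=0,
            max_nodule_diameter_mm=None,
        )
        flex.append("esophageal_varices")
    elif category == "best_supportive_care":
        if rng.random() < 0.75:  # frail patient
            ecog, child = int(rng.integers(3, 5)), int(rng.integers(5, 10))
            p["vascular_invasion"] = bool(rng.random() < 0.25)
            p["metastatic_disease"] = bool(rng.random() < 0.25)
            flex += ["vascular_invasion", "metastatic_disease"]
        else:  # decompensated, transplant-ineligible
            ecog, child = int(rng.integers(0, 3)), int(rng.integers(13, 16))
        p.update(
            esophageal_varices=free(),
            ecog_ps=ecog,
            child_pugh_score=child,
            n_nodules=int(rng.integers(1, 7)),
            max_nodule_diameter_mm=float(rng.integers(15, 91)),
        )
        flex.append("esophageal_varices")
    elif category == "systemic_therapy":
        invasion = bool(rng.random() < 0.7)
        p.update(
            vascular_invasion=invasion,
            metastatic_disease=(not invasion) or bool(rng.random() < 0.3),
            esophageal_varices=free(),
            ecog_ps=int(rng.integers(0, 3)),
            child_pugh_score=int(rng.integers(5, 10)),
            n_nodules=int(rng.integers(1, 7)),
            max_nodule_diameter_mm=float(rng.integers(20, 91)),
        )
        flex.append("esophageal_varices")
        if invasion and p["metastatic_disease"]:
            flex.append("metastatic_disease")
    elif category == "liver_transplantation":
        variant = rng.random()
        if variant < 0.6:
            child, varices, v_flex = int(rng.integers(7, 10)), free(), True
        elif variant < 0.8:
            child, varices, v_flex = int(rng.integers(10, 13)), free(), True
        else:  # compensated but with portal hypertension
            child, varices, v_flex = int(rng.integers(5, 7)), True, False
        p.update(
            esophageal_varices=varices,
            ecog_ps=int(rng.integers(0, 2)),
            child_pugh_score=child,
            n_nodules=int(rng.integers(1, 4)),
            max_nodule_diameter_mm=float(rng.integers(15, 51)),
        )
        if v_flex:
            flex.append("esophageal_varices")
    elif category == "surgical_resection":
        p.update(
            esophageal_varices=False,
            ecog_ps=int(rng.integers(0, 2)),
            child_pugh_score=int(rng.integers(5, 7)),
            n_nodules=1,
            max_nodule_diameter_mm=float(rng.integers(20, 81)),
        )
    elif category == "ablation":
        p.update(
            esophageal_varices=free(),
            ecog_ps=2,
            child_pugh_score=int(rng.integers(5, 10)),
            n_nodules=int(rng.integers(1, 4)),
            max_nodule_diameter_mm=float(rng.integers(10, 31)),
        )
        flex.append("esophageal_varices")
    elif category == "transarterial_treatment":
        if rng.random() < 0.7:
            child, varices, v_flex = int(rng.integers(7, 10)), free(), True
        else:
            child, varices, v_flex = int(rng.integers(5, 7)), True, False
        p.update(
            esophageal_varices=varices,
            ecog_ps=int(rng.integers(0, 3)),
            child_pugh_score=child,
            n_nodules=int(rng.integers(2, 9)),
            max_nodule_diameter_mm=float(rng.integers(55, 91)),
        )
        if v_flex:
            flex.append("esophageal_varices")
    else:
        raise ConfigurationError(f"unknown treatment category: {category!r}")
    return p, flex


def _base_complexity(p: dict) -> int:
    """Complexity score before the free numeric knobs (AFP/MELD/albumin)."""
    child = p["child_pugh_score"]
    score = 0
    if 7 <= child <= 9:
        score += 1
    elif child >= 10:
        score += 2
    if p["ecog_ps"] >= 2:
        score += 1
    for c in (
        "esophageal_varices",
        "severe_comorbidities",
        "vascular_invasion",
        "metastatic_disease",
    ):
        if p[c]:
            score += 1
    return score


def generate_gold(config: GeneratorConfig, case_index: int) -> GoldRecord:
    """Deterministic gold profile for one case.

    The treatment category and complexity grade are drawn from the cohort
    marginals; the profile is then constructed so that the reference rule
    table reproduces both. Deterministic given ``(config.seed, case_index)``.
    """
    config.validate()
    if case_index >= config.n_cases:
        raise ConfigurationError(
            f"case_index {case_index} out of range for n_cases={config.n_cases}"
        )
    rng = _case_rng(config.seed, case_index)

    categories = sorted(config.marginals)
    probs = np.array([config.marginals[c] for c in categories])
    category = str(rng.choice(categories, p=probs / probs.sum()))
    bands = sorted(config.complexity_marginals)
    bprobs = np.array([config.complexity_marginals[b] for b in bands])
    band = str(rng.choice(bands, p=bprobs / bprobs.sum()))
    lo, hi = _BAND_BOUNDS[band]

    profile = None
    extra = 0
    for _ in range(80):
        candidate, flex = _draw_structural(category, rng, config.negation_rate)
        base = _base_complexity(candidate)
        # Steer with flexible findings first: flipping them never changes
        # the treatment allocation, only the complexity score.
        for name in flex:
            if base <= hi:
                break
            if candidate[name]:
                candidate[name] = False
                base -= 1
        if base == 0 and lo >= 4:
            candidate["severe_comorbidities"] = True
            base = 1
        if base > hi:
            continue
        need = max(0, lo - base)
        if need <= 3:  # three free +1 knobs: AFP > 400, MELD >= 15, albumin < 2.8
            profile, extra = candidate, need
            break
    if profile is None:  # keep the treatment category, concede the band
        profile, _ = _draw_structural(category, rng, config.negation_rate)
        extra = 0

    knobs = list(rng.permutation(["afp", "meld", "albumin"])[:extra])
    if "afp" in knobs:
        afp = round(float(rng.uniform(450.0, 4000.0)), 1)
    else:
        afp = round(min(400.0, float(rng.lognormal(math.log(20.0), 1.4))), 1)
        afp = max(afp, 1.0)
    meld = int(rng.integers(15, 27)) if "meld" in knobs else int(rng.integers(6, 15))
    if "albumin" in knobs:
        albumin = round(float(rng.uniform(2.0, 2.7)), 1)
    else:
        albumin = round(float(rng.uniform(3.0, 4.6)), 1)

    age = int(np.clip(round(rng.normal(config.mean_age, config.sd_age)), 25, 94))
    if category == "liver_transplantation":
        age = min(age, 69)
    sex = "male" if rng.random() < config.male_fraction else "female"

    gold = GoldRecord(
        case_id=f"case-{config.seed}-{case_index:05d}",
        age=age,
        sex=sex,
        ecog_ps=profile["ecog_ps"],
        child_pugh_class=child_pugh_class_from_score(profile["child_pugh_score"]),
        child_pugh_score=profile["child_pugh_score"],
        meld_score=meld,
        albumin_g_dl=albumin,
        afp_ng_ml=afp,
        esophageal_varices=profile["esophageal_varices"],
        severe_comorbidities=profile["severe_comorbidities"],
        previous_hcc_treatment=profile["previous_hcc_treatment"],
        complete_response_last_treatment=profile["complete_response_last_treatment"],
        n_nodules=profile["n_nodules"],
        max_nodule_diameter_mm=profile["max_nodule_diameter_mm"],
        vascular_invasion=profile["vascular_invasion"],
        metastatic_disease=profile["metastatic_disease"],
        reference_decision=DecisionTriple("", "", ""),
    )
    gold.reference_decision = assign_reference_decision(gold)
    gold.validate()
    if gold.reference_decision.treatment != category:
        raise RuntimeError(
            f"generator produced a profile inconsistent with its category: "
            f"{category} -> {gold.reference_decision.treatment}"
        )
    return gold


# ---------------------------------------------------------------------------
# Note rendering
# ---------------------------------------------------------------------------


def _fmt_number(value: float, style: str) -> str:
    """Format a number; comma style uses '.' thousands and ',' decimals."""
    if float(value) == int(value) and abs(value) < 1e6:
        text = f"{int(value):,}" if style == "comma" else str(int(value))
        return text.replace(",", ".") if style == "comma" else text
    text = f"{value:,.1f}"
    if style == "comma":
        return text.replace(",", "\0").replace(".", ",").replace("\0", ".")
    return text


_EN = {
    "header": "Clinical note - case {case_id}.",
    "demo": "The patient is a {age}-year-old {sex}.",
    "sex": {"male": "man", "female": "woman"},
    "severe_comorbidities": (
        "Severe comorbidities are documented (ischemic heart disease).",
        "No severe comorbidities.",
    ),
    "previous_hcc_treatment": (
        "Previous HCC treatment: transarterial chemoembolization in the past.",
        "No previous HCC treatment.",
    ),
    "complete_response_last_treatment": (
        "Complete response to the last treatment was achieved.",
        "No complete response to the last treatment; residual disease noted.",
    ),
    "esophageal_varices": (
        "Esophageal varices are seen on endoscopy.",
        "No esophageal varices on endoscopy.",
    ),
    "vascular_invasion": (
        "Portal vein thrombosis is documented.",
        "No portal vein thrombosis.",
    ),
    "metastatic_disease": (
        "Metastatic disease is documented in the lungs.",
        "No evidence of metastatic disease.",
    ),
    "child_pugh_score": "Child-Pugh score {v} (class {cls}).",
    "child_pugh_compound": "Child-Pugh {cls}{v}.",
    "meld_score": "MELD score {v}.",
    "albumin_g_dl": "Serum albumin {v} g/dl.",
    "afp_ng_ml": "AFP {v} ng/ml.",
    "ecog_ps": "ECOG performance status {v}.",
    "imaging_header": "Imaging ({modality}, {year}):",
    "modalities": ("CT scan", "MRI", "contrast ultrasound"),
    "nodules": "{n} hepatic nodules are identified; the largest lesion measures {d}.",
    "nodules_nodim": "{n} hepatic nodules are identified, under evaluation.",
    "no_nodules": "No hepatic nodules are identified.",
    "mm": "{v} mm",
    "cm": "{v} cm",
}

_IT = {
    "header": "Nota clinica - caso {case_id}.",
    "demo": "Paziente di {age} anni, sesso {sex}.",
    "sex": {"male": "maschile", "female": "femminile"},
    "severe_comorbidities": (
        "Comorbidita severe documentate (cardiopatia ischemica).",
        "Assenza di comorbidita severe.",
    ),
    "previous_hcc_treatment": (
        "Pregresso trattamento per HCC: chemioembolizzazione.",
        "Nessun pregresso trattamento per HCC.",
    ),
    "complete_response_last_treatment": (
        "Risposta completa all'ultimo trattamento.",
        "Nessuna risposta completa all'ultimo trattamento.",
    ),
    "esophageal_varices": (
        "Varici esofagee presenti alla EGDS.",
        "Assenza di varici esofagee.",
    ),
    "vascular_invasion": (
        "Trombosi della vena porta.",
        "Non si evidenzia trombosi della vena porta.",
    ),
    "metastatic_disease": (
        "Malattia metastatica polmonare.",
        "Assenza di malattia metastatica.",
    ),
    "child_pugh_score": "Punteggio di Child-Pugh {v} (classe {cls}).",
    "child_pugh_compound": "Child-Pugh {cls}{v}.",
    "meld_score": "MELD {v}.",
    "albumin_g_dl": "Albumina sierica {v} g/dl.",
    "afp_ng_ml": "AFP {v} ng/ml.",
    "ecog_ps": "ECOG PS {v}.",
    "imaging_header": "Imaging (TC, {year}):" ,
    "modalities": ("TC",),
    "nodules": "{n} noduli epatici; il nodulo maggiore misura {d}.",
    "nodules_nodim": "{n} noduli epatici in corso di valutazione.",
    "no_nodules": "Assenza di noduli epatici.",
    "mm": "{v} mm",
    "cm": "{v} cm",
}

_TEMPLATES = {"en": _EN, "it": _IT}

#: Concepts rendered in the narrative body vs. the latest imaging section.
_BODY_CONCEPTS = (
    "severe_comorbidities",
    "previous_hcc_treatment",
    "complete_response_last_treatment",
    "esophageal_varices",
)
_IMAGING_CONCEPTS = ("vascular_invasion", "metastatic_disease")

LATEST_IMAGING_YEAR = 2024


def render_note(
    gold: GoldRecord, config: GeneratorConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[ClinicalNote, RenderInfo]:
    """Render a gold profile into a narrative note.

    Negative findings are written as negated mentions (a negation phrase
    within the three-token window of the concept term). When several dated
    imaging sections are emitted, only the most recent one carries the gold
    nodule diameter; older sections carry decoy values differing by at
    least 5 mm.
    """
    if config.language not in _TEMPLATES:
        raise ConfigurationError(f"unknown language template set: {config.language!r}")
    t = _TEMPLATES[config.language]
    style = "comma" if config.language == "it" else "dot"
    if rng is None:
        rng = _case_rng(config.seed, 0, stream=1)

    rendered: set = set()
    negated: set = set()

    def keep(name: str) -> bool:
        if rng.random() < config.missingness_rate:
            return False
        rendered.add(name)
        return True

    body: List[str] = [t["header"].format(case_id=gold.case_id)]
    body.append(t["demo"].format(age=gold.age, sex=t["sex"][gold.sex]))

    history: List[str] = []
    for name in _BODY_CONCEPTS:
        if not keep(name):
            continue
        affirmed, negated_tpl = t[name]
        if getattr(gold, name):
            history.append(affirmed)
        else:
            history.append(negated_tpl)
            negated.add(name)
    if history:
        body.append(" ".join(history))

    labs: List[str] = []
    if keep("child_pugh_score"):
        if rng.random() < 0.3:
            labs.append(
                t["child_pugh_compound"].format(cls=gold.child_pugh_class, v=gold.child_pugh_score)
            )
        else:
            labs.append(
                t["child_pugh_score"].format(v=gold.child_pugh_score, cls=gold.child_pugh_class)
            )
    if keep("meld_score"):
        labs.append(t["meld_score"].format(v=gold.meld_score))
    if keep("albumin_g_dl"):
        labs.append(t["albumin_g_dl"].format(v=_fmt_number(gold.albumin_g_dl, style)))
    if keep("afp_ng_ml"):
        labs.append(t["afp_ng_ml"].format(v=_fmt_number(gold.afp_ng_ml, style)))
    if keep("ecog_ps"):
        labs.append(t["ecog_ps"].format(v=gold.ecog_ps))
    if labs:
        body.append(" ".join(labs))

    # Imaging sections, oldest first; the latest carries the gold diameter.
    lo, hi = config.n_imaging_sections_range
    n_sections = int(rng.integers(lo, hi + 1))
    years = [LATEST_IMAGING_YEAR - (n_sections - 1 - i) for i in range(n_sections)]
    diameter_rendered = gold.max_nodule_diameter_mm is not None and keep(
        "max_nodule_diameter_mm"
    )
    decoys: List[float] = []
    for i, year in enumerate(years):
        latest = i == n_sections - 1
        modality = str(rng.choice(t["modalities"]))
        header = t["imaging_header"].format(modality=modality, year=year)
        lines = [header]
        if gold.n_nodules == 0:
            lines.append(t["no_nodules"])
        else:
            if latest:
                dim_value = gold.max_nodule_diameter_mm if diameter_rendered else None
            else:
                # decoy differs from gold by at least 5 mm
                delta = float(rng.integers(5, 16)) * (1 if rng.random() < 0.5 else -1)
                dim_value = max(5.0, float(gold.max_nodule_diameter_mm) + delta)
                if abs(dim_value - gold.max_nodule_diameter_mm) < 5:
                    dim_value = gold.max_nodule_diameter_mm + 5.0
                decoys.append(dim_value)
            if dim_value is None:
                lines.append(t["nodules_nodim"].format(n=gold.n_nodules))
            else:
                if dim_value == int(dim_value) and rng.random() < 0.35:
                    dim_text = t["cm"].format(v=_fmt_number(dim_value / 10.0, style))
                else:
                    dim_text = t["mm"].format(v=_fmt_number(dim_value, style))
                lines.append(t["nodules"].format(n=gold.n_nodules, d=dim_text))
        if latest:
            for name in _IMAGING_CONCEPTS:
                if not keep(name):
                    continue
                affirmed, negated_tpl = t[name]
                if getattr(gold, name):
                    lines.append(affirmed)
                else:
                    lines.append(negated_tpl)
                    negated.add(name)
        body.append(" ".join(lines))

    text = "\n\n".join(body)
    note = ClinicalNote(case_id=gold.case_id, text=text, language=config.language)
    info = RenderInfo(
        case_id=gold.case_id,
        rendered_fields=rendered,
        negated_concepts=negated,
        decimal_style=style,
        imaging_years=years,
        decoy_diameters=decoys,
    )
    return note, info


def generate_case(config: GeneratorConfig, case_index: int) -> CaseBundle:
    gold = generate_gold(config, case_index)
    rng = _case_rng(config.seed, case_index, stream=1)
    note, info = render_note(gold, config, rng=rng)
    return CaseBundle(note=note, gold=gold, render=info)


def generate_bundles(config: GeneratorConfig) -> List[CaseBundle]:
    config.validate()
    return [generate_case(config, i) for i in range(config.n_cases)]


def generate_corpus(config: GeneratorConfig) -> Iterator[Tuple[ClinicalNote, GoldRecord]]:
    """Stream of ``(note, gold)`` pairs, reproducible under the seed."""
    config.validate()
    for i in range(config.n_cases):
        bundle = generate_case(config, i)
        yield bundle.note, bundle.gold
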