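"""Core domain types exchanged between the pipeline stages.

The unit of exchange is the :class:`StructuredRecord`: the six tri-state
clinical concepts plus six numerical parameters that drive hepatocellular
carcinoma (HCC) management decisions. Extraction stages produce it from
narrative notes; the decision stage consumes its rendered form.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

#: Sentinel for a parameter that a note (or an extractor) does not report.
NOT_REPORTED = "not_reported"

#: Tri-state values for categorical clinical concepts.
PRESENT = "present"
ABSENT = "absent"

CONCEPT_FIELDS = (
    "vascular_invasion",
    "severe_comorbidities",
    "metastatic_disease",
    "previous_hcc_treatment",
    "complete_response_last_treatment",
    "esophageal_varices",
)

NUMERIC_FIELDS = (
    "afp_ng_ml",
    "albumin_g_dl",
    "ecog_ps",
    "child_pugh_score",
    "meld_score",
    "max_nodule_diameter_mm",
)

ALL_FIELDS = CONCEPT_FIELDS + NUMERIC_FIELDS

#: Canonical line labels used when a record is serialized as a structured
#: note ("Field: value" lines) and when model output is parsed back.
FIELD_LABELS = {
    "vascular_invasion": "Vascular invasion",
    "severe_comorbidities": "Severe comorbidities",
    "metastatic_disease": "Metastatic disease",
    "previous_hcc_treatment": "Previous HCC treatment",
    "complete_response_last_treatment": "Complete response to last treatment",
    "esophageal_varices": "Esophageal varices",
    "afp_ng_ml": "AFP (ng/ml)",
    "albumin_g_dl": "Albumin (g/dl)",
    "ecog_ps": "ECOG performance status",
    "child_pugh_score": "Child-Pugh score",
    "meld_score": "MELD score",
    "max_nodule_diameter_mm": "Maximum nodule diameter (mm)",
}

TREATMENTS = (
    "liver_transplantation",
    "surgical_resection",
    "ablation",
    "transarterial_treatment",
    "systemic_therapy",
    "best_supportive_care",
    "follow_up_continuation",
)

COMPLEXITY_LEVELS = ("low", "moderate", "high")

MDT_LEVELS = ("yes", "no")

#: Sentinel label for generator output that could not be mapped to any
#: canonical category; always scored as incorrect.
UNPARSEABLE = "unparseable"


@dataclass(frozen=True)
class DecisionTriple:
    """Treatment allocation, clinical complexity grade and MDT referral."""

    treatment: str
    complexity: str
    mdt: str

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class GoldRecord:
    """Full ground-truth clinical profile of one synthetic case."""

    case_id: str
    age: int
    sex: str  # "male" | "female"
    ecog_ps: int
    child_pugh_class: str  # "A" | "B" | "C"
    child_pugh_score: int
    meld_score: int
    albumin_g_dl: float
    afp_ng_ml: float
    esophageal_varices: bool
    severe_comorbidities: bool
    previous_hcc_treatment: bool
    complete_response_last_treatment: bool
    n_nodules: int
    max_nodule_diameter_mm: Optional[float]
    vascular_invasion: bool
    metastatic_disease: bool
    reference_decision: DecisionTriple

    def validate(self) -> None:
        cls_ranges = {"A": (5, 6), "B": (7, 9), "C": (10, 15)}
        lo, hi = cls_ranges[self.child_pugh_class]
        if not lo <= self.child_pugh_score <= hi:
            raise ValueError(
                f"Child-Pugh score {self.child_pugh_score} inconsistent "
                f"with class {self.child_pugh_class}"
            )
        if not 0 <= self.ecog_ps <= 4:
            raise ValueError(f"ECOG-PS out of range: {self.ecog_ps}")
        if not 6 <= self.meld_score <= 40:
            raise ValueError(f"MELD out of range: {self.meld_score}")
        if self.complete_response_last_treatment and not self.previous_hcc_treatment:
            raise ValueError("complete response implies a previous treatment")
        if (self.n_nodules >= 1) != (self.max_nodule_diameter_mm is not None):
            raise ValueError("diameter must be present iff n_nodules >= 1")

    def as_dict(self) -> dict:
        d = asdict(self)
        d["reference_decision"] = self.reference_decision.as_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GoldRecord":
        d = dict(d)
        d["reference_decision"] = DecisionTriple(**d["reference_decision"])
        return cls(**d)


@dataclass
class ClinicalNote:
    """A narrative clinical report for one case."""

    case_id: str
    text: str
    language: str = "en"


@dataclass
class StructuredRecord:
    """The 12 extraction targets with per-field provenance.

    Concept fields take values ``present`` / ``absent`` / ``not_reported``;
    numeric fields hold a float or ``not_reported``. ``provenance`` tags
    each *reported* field with the extractor that produced it
    (``regex`` | ``llm`` | ``fallback_regex`` | ``gold``).
    """

    vascular_invasion: str = NOT_REPORTED
    severe_comorbidities: str = NOT_REPORTED
    metastatic_disease: str = NOT_REPORTED
    previous_hcc_treatment: str = NOT_REPORTED
    complete_response_last_treatment: str = NOT_REPORTED
    esophageal_varices: str = NOT_REPORTED

    afp_ng_ml: object = NOT_REPORTED
    albumin_g_dl: object = NOT_REPORTED
    ecog_ps: object = NOT_REPORTED
    child_pugh_score: object = NOT_REPORTED
    meld_score: object = NOT_REPORTED
    max_nodule_diameter_mm: object = NOT_REPORTED

    provenance: dict = field(default_factory=dict)

    def get(self, name: str):
        return getattr(self, name)

    def set(self, name: str, value, provenance: Optional[str] = None) -> None:
        setattr(self, name, value)
        if provenance is not None and value != NOT_REPORTED:
            self.provenance[name] = provenance

    def reported_fields(self) -> list:
        return [f for f in ALL_FIELDS if self.get(f) != NOT_REPORTED]

    def validate(self) -> None:
        for f in NUMERIC_FIELDS:
            v = self.get(f)
            if v == NOT_REPORTED:
                continue
            v = float(v)
            if not (v == v and v >= 0 and v != float("inf")):
                raise ValueError(f"{f}: non-finite or negative value {v}")
        for f in CONCEPT_FIELDS:
            if self.get(f) not in (PRESENT, ABSENT, NOT_REPORTED):
                raise ValueError(f"{f}: invalid tri-state value {self.get(f)!r}")

    def as_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StructuredRecord":
        return cls(**d)

    def __eq__(self, other) -> bool:  # provenance is metadata, not content
        if not isinstance(other, StructuredRecord):
            return NotImplemented
        return all(self.get(f) == other.get(f) for f in ALL_FIELDS)


def child_pugh_class_from_score(score: float) -> str:
    """Map a Child-Pugh score (5-15) to its class (A: 5-6, B: 7-9, C: 10-15)."""
    if score <= 6:
        return "A"
    if score <= 9:
        return "B"
    return "C"


def gold_to_structured(gold: GoldRecord) -> StructuredRecord:
    """Project a gold profile onto the 12 extraction targets.

    Booleans become ``present`` / ``absent``; the nodule diameter is
    ``not_reported`` when the case has no measurable lesion.
    """
    rec = StructuredRecord()
    for f in CONCEPT_FIELDS:
        rec.set(f, PRESENT if getattr(gold, f) else ABSENT, provenance="gold")
    rec.set("afp_ng_ml", float(gold.afp_ng_ml), provenance="gold")
    rec.set("albumin_g_dl", float(gold.albumin_g_dl), provenance="gold")
    rec.set("ecog_ps", float(gold.ecog_ps), provenance="gold")
    rec.set("child_pugh_score", float(gold.child_pugh_score), provenance="gold")
    rec.set("meld_score", float(gold.meld_score), provenance="gold")
    if gold.max_nodule_diameter_mm is not None:
        rec.set(
            "max_nodule_diameter_mm",
            float(gold.max_nodule_diameter_mm),
            provenance="gold",
        )
    return rec
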