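"""Reference-decision rule table for the synthetic corpus.

The real-world decisions the framework is benchmarked against are made by
clinicians; the synthetic corpus needs a *deterministic, documented,
hepatology-plausible* stand-in so the decision stage can be tested in a
closed loop. The table below is that stand-in — it is NOT a reconstruction
of any institutional protocol, and it is deliberately keyed only to the 12
extraction targets so that a structured note carries every determinant of
its own reference decision.

Treatment allocation (first matching rule wins)
-----------------------------------------------
1.  Previous treatment with complete response, no measurable lesion, no
    vascular invasion, no metastases        -> follow_up_continuation
2.  ECOG-PS >= 3                            -> best_supportive_care
3.  Vascular invasion or metastases with preserved liver function
    (Child-Pugh <= 9)                       -> systemic_therapy
4.  Lesion <= 50 mm, ECOG <= 1, no invasion/metastases, and either
    decompensation (Child-Pugh 7-12) or portal hypertension (varices)
                                            -> liver_transplantation
5.  Child-Pugh A, no varices, ECOG <= 1, measurable lesion,
    no invasion/metastases                  -> surgical_resection
6.  Lesion <= 30 mm, Child-Pugh <= 9, ECOG <= 2
                                            -> ablation
7.  Measurable lesion, Child-Pugh <= 9, ECOG <= 2
                                            -> transarterial_treatment
8.  Otherwise (decompensated, transplant-ineligible, or no evaluable
    disease)                                -> best_supportive_care

Clinical complexity: an additive borderline-criteria score; each of
{Child-Pugh B (+1) / C (+2), ECOG 2 (+1), ECOG >= 3 (+1), varices,
severe comorbidities, vascular invasion, metastases, AFP > 400 ng/ml,
MELD >= 15, albumin < 2.8 g/dl} adds one point.
low: score <= 1; moderate: 2-3; high: >= 4.

MDT referral: every transplant allocation; resections with comorbidity,
varices or MELD >= 10; any other active treatment in a high-complexity case.
"""

from __future__ import annotations

from .records import (
    ABSENT,
    NOT_REPORTED,
    PRESENT,
    DecisionTriple,
    GoldRecord,
    StructuredRecord,
    gold_to_structured,
)

#: Complexity score thresholds: low <= LOW_MAX < moderate <= MOD_MAX < high.
COMPLEXITY_LOW_MAX = 1
COMPLEXITY_MODERATE_MAX = 3

# Defaults used when a decision-relevant field is not reported, so the rule
# stays a total function on arbitrary extracted records.
_DEFAULTS = {
    "ecog_ps": 1.0,
    "child_pugh_score": 6.0,
    "meld_score": 10.0,
    "afp_ng_ml": 0.0,
    "albumin_g_dl": 3.5,
}


def _num(record: StructuredRecord, name: str):
    v = record.get(name)
    if v == NOT_REPORTED:
        return _DEFAULTS.get(name)
    return float(v)


def _is(record: StructuredRecord, name: str) -> bool:
    return record.get(name) == PRESENT


def allocate_treatment(record: StructuredRecord) -> str:
    ecog = _num(record, "ecog_ps")
    child = _num(record, "child_pugh_score")
    diameter = record.get("max_nodule_diameter_mm")
    has_lesion = diameter != NOT_REPORTED
    diameter = float(diameter) if has_lesion else None
    invasion = _is(record, "vascular_invasion")
    mets = _is(record, "metastatic_disease")
    varices = _is(record, "esophageal_varices")

    if (
        _is(record, "previous_hcc_treatment")
        and _is(record, "complete_response_last_treatment")
        and not has_lesion
        and not invasion
        and not mets
    ):
        return "follow_up_continuation"
    if ecog >= 3:
        return "best_supportive_care"
    if (invasion or mets) and child <= 9:
        return "systemic_therapy"
    if invasion or mets:  # advanced disease on decompensated cirrhosis
        return "best_supportive_care"
    if (
        has_lesion
        and diameter <= 50
        and ecog <= 1
        and (7 <= child <= 12 or varices)
        and child <= 12
    ):
        return "liver_transplantation"
    if has_lesion and child <= 6 and not varices and ecog <= 1:
        return "surgical_resection"
    if has_lesion and diameter <= 30 and child <= 9 and ecog <= 2:
        return "ablation"
    if has_lesion and child <= 9 and ecog <= 2:
        return "transarterial_treatment"
    return "best_supportive_care"


def complexity_score(record: StructuredRecord) -> int:
    child = _num(record, "child_pugh_score")
    ecog = _num(record, "ecog_ps")
    score = 0
    if 7 <= child <= 9:
        score += 1
    elif child >= 10:
        score += 2
    if ecog == 2:
        score += 1
    elif ecog >= 3:
        score += 1
    for concept in (
        "esophageal_varices",
        "severe_comorbidities",
        "vascular_invasion",
        "metastatic_disease",
    ):
        if _is(record, concept):
            score += 1
    if _num(record, "afp_ng_ml") > 400:
        score += 1
    if _num(record, "meld_score") >= 15:
        score += 1
    if _num(record, "albumin_g_dl") < 2.8:
        score += 1
    return score


def grade_complexity(record: StructuredRecord) -> str:
    s = complexity_score(record)
    if s <= COMPLEXITY_LOW_MAX:
        return "low"
    if s <= COMPLEXITY_MODERATE_MAX:
        return "moderate"
    return "high"


def refer_to_mdt(record: StructuredRecord, treatment: str, complexity: str) -> str:
    if treatment == "liver_transplantation":
        return "yes"
    if treatment == "surgical_resection" and (
        _is(record, "severe_comorbidities")
        or _is(record, "esophageal_varices")
        or _num(record, "meld_score") >= 10
    ):
        return "yes"
    if complexity == "high" and treatment in (
        "surgical_resection",
        "ablation",
        "transarterial_treatment",
        "systemic_therapy",
    ):
        return "yes"
    return "no"


def decide_from_record(record: StructuredRecord) -> DecisionTriple:
    """Total decision function over structured records."""
    treatment = allocate_treatment(record)
    complexity = grade_complexity(record)
    mdt = refer_to_mdt(record, treatment, complexity)
    return DecisionTriple(treatment=treatment, complexity=complexity, mdt=mdt)


def assign_reference_decision(gold: GoldRecord) -> DecisionTriple:
    """Reference decision for a gold profile.

    Defined as the rule table applied to the profile's projection onto the
    12 extraction targets, so a faithfully extracted structured note always
    reproduces the reference decision.
    """
    return decide_from_record(gold_to_structured(gold))
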