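"""Pattern-based extraction: negation windows, numeric adjacency, imaging
recency, and equivalence with a brute-force scan oracle."""

import random

import pytest

from hepadecide.records import ABSENT, NOT_REPORTED, PRESENT, ALL_FIELDS, gold_to_structured
from hepadecide.regex_extract import (
    detect_concept,
    extract_nodule_diameter,
    extract_numeric,
    regex_extract_all,
)
from hepadecide.lexicon import TermDictionary
from hepadecide.textproc import tokenize


# ---------------------------------------------------------------------------
# Concept detection and negation windows
# ---------------------------------------------------------------------------


def test_italian_thrombosis_pattern_is_present(dicts_it):
    assert detect_concept(
        "trombosi della vena porta", dicts_it.concepts["vascular_invasion"]
    ) == PRESENT


def test_negator_measured_from_match_span(dicts_en):
    # "no" is 4 tokens from "thrombosis" but 3 before the span start
    assert detect_concept(
        "no evidence of portal vein thrombosis", dicts_en.concepts["vascular_invasion"]
    ) == ABSENT


def test_unmentioned_concept_is_not_reported(dicts_en):
    assert detect_concept(
        "liver is cirrhotic", dicts_en.concepts["vascular_invasion"]
    ) == NOT_REPORTED


@pytest.mark.parametrize(
    "text,expected",
    [
        ("no alpha beta varices", ABSENT),        # negator exactly 3 before
        ("no alpha beta gamma varices", PRESENT),  # 4 before: outside window
        ("varices alpha beta no", ABSENT),         # exactly 3 after
        ("varices alpha beta gamma no", PRESENT),  # 4 after: outside window
    ],
)
def test_window_boundary_symmetric(dicts_en, text, expected):
    assert detect_concept(text, dicts_en.concepts["esophageal_varices"]) == expected


def test_window_stops_at_sentence_boundary(dicts_en):
    assert detect_concept(
        "no. esophageal varices", dicts_en.concepts["esophageal_varices"]
    ) == PRESENT


def test_affirmation_dominates_over_negated_restatement(dicts_en):
    text = "No esophageal varices previously. Esophageal varices are seen today."
    assert detect_concept(text, dicts_en.concepts["esophageal_varices"]) == PRESENT


def test_detection_independent_of_term_entry_order(dicts_en):
    base = dicts_en.concepts["vascular_invasion"]
    text = "No portal vein thrombosis; vascular invasion suspected."
    shuffled = TermDictionary(
        concept_or_parameter=base.concept_or_parameter,
        terms=list(reversed(base.terms)),
        negators=base.negators,
        window=base.window,
    )
    assert detect_concept(text, base) == detect_concept(text, shuffled)


def brute_force_concept(text: str, dictionary: TermDictionary) -> str:
    """Independent oracle: enumerate all (term, position) matches and all
    negator positions with explicit loops."""
    tokens = tokenize(text)
    words = [t.text for t in tokens]
    matches = []
    for term in dictionary.token_terms:
        k = len(term)
        for i in range(len(words) - k + 1):
            if all(words[i + j] == term[j] for j in range(k)):
                matches.append((i, i + k))
    if not matches:
        return NOT_REPORTED
    negs = {i for i, w in enumerate(words) if w in set(dictionary.negators)}
    w = dictionary.window
    for start, end in matches:
        negated = False
        for i in negs:
            same_sentence_before = (
                i < start and start - i <= w and tokens[i].sentence == tokens[start].sentence
            )
            same_sentence_after = (
                i >= end and i - end + 1 <= w and tokens[i].sentence == tokens[end - 1].sentence
            )
            if same_sentence_before or same_sentence_after:
                negated = True
                break
        if not negated:
            return PRESENT
    return ABSENT


def test_concept_detection_matches_brute_force_oracle(dicts_en):
    """On notes composed of dictionary surface forms, negators and filler,
    windowed detection equals exhaustive (term, negator, offset) scanning."""
    rng = random.Random(1234)
    terms = [t for d in dicts_en.concepts.values() for t in d.terms]
    pieces = terms + list(dicts_en.negators) + ["alpha", "beta", "gamma", ".", ";"]
    for _ in range(300):
        text = " ".join(rng.choice(pieces) for _ in range(rng.randint(1, 25)))
        for name, dictionary in dicts_en.concepts.items():
            assert detect_concept(text, dictionary) == brute_force_concept(text, dictionary), (
                text, name,
            )


# ---------------------------------------------------------------------------
# Numeric extraction
# ---------------------------------------------------------------------------


def _spec(dicts, name):
    return dicts.numerics[name]


@pytest.mark.parametrize(
    "text,expected",
    [
        ("MELD score 12", 12.0),
        ("12 is the MELD", 12.0),
        ("MELD pending", NOT_REPORTED),
        ("no MELD documented", NOT_REPORTED),
    ],
)
def test_meld_adjacency(dicts_en, text, expected):
    assert extract_numeric(text, _spec(dicts_en, "meld_score")) == expected


def test_no_cross_capture_between_markers(dicts_en):
    text = "MELD 12; Child-Pugh 8"
    assert extract_numeric(text, _spec(dicts_en, "meld_score")) == 12.0
    assert extract_numeric(text, _spec(dicts_en, "child_pugh_score")) == 8.0


def test_tie_prefers_value_following_keyword(dicts_en):
    assert extract_numeric("10 MELD 12", _spec(dicts_en, "meld_score")) == 12.0


def test_child_pugh_compound_parses_to_score(dicts_en):
    assert extract_numeric("Child-Pugh B7.", _spec(dicts_en, "child_pugh_score")) == 7.0
    assert extract_numeric("Child-Pugh class A 5", _spec(dicts_en, "child_pugh_score")) == 5.0


def test_out_of_domain_values_are_not_reported(dicts_en):
    assert extract_numeric("ECOG performance status 9", _spec(dicts_en, "ecog_ps")) == NOT_REPORTED


def test_italian_decimal_comma(dicts_it):
    assert extract_numeric("Albumina sierica 3,2 g/dl", _spec(dicts_it, "albumin_g_dl")) == 3.2
    assert extract_numeric("AFP 1.204,5 ng/ml", _spec(dicts_it, "afp_ng_ml")) == 1204.5


# ---------------------------------------------------------------------------
# Nodule diameter recency
# ---------------------------------------------------------------------------


def test_most_recent_imaging_section_wins(dicts_en):
    text = (
        "Imaging (CT scan, 2022): nodule of 20 mm.\n\n"
        "Imaging (MRI, 2024): nodule of 32 mm."
    )
    assert extract_nodule_diameter(text, dicts_en) == 32.0
    flipped = (
        "Imaging (MRI, 2024): nodule of 32 mm.\n\n"
        "Imaging (CT scan, 2022): nodule of 20 mm."
    )
    assert extract_nodule_diameter(flipped, dicts_en) == 32.0


def test_cm_normalized_to_mm(dicts_en):
    assert extract_nodule_diameter(
        "Imaging (ultrasound, 2023): lesion of 3.1 cm.", dicts_en
    ) == pytest.approx(31.0)


def test_unit_invariance(dicts_en):
    a = extract_nodule_diameter("Imaging (CT scan, 2023): lesion of 3.1 cm.", dicts_en)
    b = extract_nodule_diameter("Imaging (CT scan, 2023): lesion of 31 mm.", dicts_en)
    assert a == b


def test_no_imaging_section_not_reported(dicts_en):
    assert extract_nodule_diameter("MELD 12. AFP 5 ng/ml.", dicts_en) == NOT_REPORTED


def test_year_tie_broken_by_document_position(dicts_en):
    text = (
        "Imaging (CT scan, 2024): nodule of 20 mm.\n\n"
        "Imaging (MRI, 2024): nodule of 40 mm."
    )
    assert extract_nodule_diameter(text, dicts_en) == 40.0


def test_maximum_dimension_within_section(dicts_en):
    text = "Imaging (CT scan, 2024): nodules of 12 mm, 3 cm and 25 mm."
    assert extract_nodule_diameter(text, dicts_en) == 30.0


# ---------------------------------------------------------------------------
# Whole-record extraction against generator bookkeeping
# ---------------------------------------------------------------------------


def test_clean_note_closed_loop(dicts_en):
    from hepadecide import GeneratorConfig, generate_bundles

    cfg = GeneratorConfig(n_cases=25, seed=3, negation_rate=0.0, missingness_rate=0.0)
    for b in generate_bundles(cfg):
        record = regex_extract_all(b.note, dicts_en)
        assert record == gold_to_structured(b.gold)
        assert all(v == "regex" for v in record.provenance.values())


def test_mixed_corpus_agreement_matches_render_bookkeeping(small_bundles, dicts_en):
    """With mixed negation/missingness, extraction equals gold exactly on the
    fields the generator actually rendered, and is not_reported elsewhere."""
    for b in small_bundles:
        record = regex_extract_all(b.note, dicts_en)
        expected = gold_to_structured(b.gold)
        for name in ALL_FIELDS:
            if name in b.render.rendered_fields:
                assert record.get(name) == expected.get(name), (b.gold.case_id, name)
            else:
                assert record.get(name) == NOT_REPORTED, (b.gold.case_id, name)


def test_all_negated_note_yields_absent_concepts(dicts_en):
    text = (
        "No severe comorbidities. No previous HCC treatment. "
        "No complete response to the last treatment. No esophageal varices.\n\n"
        "Imaging (CT scan, 2024): No hepatic nodules. No portal vein thrombosis. "
        "No evidence of metastatic disease."
    )
    record = regex_extract_all(text, dicts_en)
    for name in (
        "vascular_invasion", "severe_comorbidities", "metastatic_disease",
        "previous_hcc_treatment", "complete_response_last_treatment",
        "esophageal_varices",
    ):
        assert record.get(name) == ABSENT
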