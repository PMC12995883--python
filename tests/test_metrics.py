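"""Agreement statistics: F1, first-decimal matching, ICC(A,1), bootstrap
CIs, accuracy, confusion matrices and median/IQR aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hepadecide.metrics import (
    aggregate_median_iqr,
    bootstrap_ci,
    confusion_matrix,
    evaluate_extraction,
    exact_match_accuracy,
    f1_categorical,
    icc_absolute_agreement,
    icc_reliability_band,
    numeric_match,
    round_half_up,
)
from hepadecide.records import ABSENT, NOT_REPORTED, PRESENT


# ---------------------------------------------------------------------------
# F1
# ---------------------------------------------------------------------------


def test_f1_perfect():
    assert f1_categorical([PRESENT, ABSENT], [PRESENT, ABSENT]) == 1.0


def test_f1_from_hand_counts():
    # TP=3, FP=1, FN=2 -> precision .75, recall .6, F1 = 2/3
    preds = [PRESENT] * 3 + [PRESENT] + [ABSENT] * 2 + [ABSENT]
    refs = [PRESENT] * 3 + [ABSENT] + [PRESENT] * 2 + [ABSENT]
    assert f1_categorical(preds, refs) == pytest.approx(2 / 3)


def test_f1_all_not_reported_is_zero():
    assert f1_categorical([NOT_REPORTED] * 4, [PRESENT] * 4) == 0.0


def test_f1_not_reported_never_counts_as_present():
    # not_reported against absent reference adds no false positive
    assert f1_categorical([PRESENT, NOT_REPORTED], [PRESENT, ABSENT]) == 1.0


def test_f1_length_mismatch_rejected():
    with pytest.raises(ValueError):
        f1_categorical([PRESENT], [PRESENT, ABSENT])


def brute_force_f1(preds, refs):
    """Independent confusion-count oracle."""
    cells = {"tp": 0, "fp": 0, "fn": 0}
    for p, r in zip(preds, refs):
        if p == PRESENT and r == PRESENT:
            cells["tp"] += 1
        if p == PRESENT and r != PRESENT:
            cells["fp"] += 1
        if p != PRESENT and r == PRESENT:
            cells["fn"] += 1
    precision = cells["tp"] / (cells["tp"] + cells["fp"]) if cells["tp"] + cells["fp"] else 0.0
    recall = cells["tp"] / (cells["tp"] + cells["fn"]) if cells["tp"] + cells["fn"] else 0.0
    return 2 * precision * recall / (precision + recall) if precision + recall else 0.0


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.sampled_from([PRESENT, ABSENT, NOT_REPORTED]),
            st.sampled_from([PRESENT, ABSENT]),
        ),
        min_size=1,
        max_size=40,
    )
)
def test_f1_matches_brute_force_confusion_counting(pairs):
    preds = [p for p, _ in pairs]
    refs = [r for _, r in pairs]
    assert f1_categorical(preds, refs) == pytest.approx(brute_force_f1(preds, refs))


# ---------------------------------------------------------------------------
# First-decimal numeric matching
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "pred,ref,expected",
    [
        (12.34, 12.3, True),  # both round to 12.3 at one decimal
        (12.3, 12.3, True),
        (12.36, 12.3, False),
        (12.5, 12.4, False),
        (5, 5.04, True),
        (5, 5.05, False),  # 5.05 rounds half-up to 5.1
        (NOT_REPORTED, 7, False),
        (7, NOT_REPORTED, False),
        (NOT_REPORTED, NOT_REPORTED, True),
    ],
)
def test_numeric_match_first_decimal(pred, ref, expected):
    assert numeric_match(pred, ref) is expected


# ---------------------------------------------------------------------------
# ICC(A,1)
# ---------------------------------------------------------------------------


def anova_icc_oracle(matrix):
    """ICC(A,1) computed with explicit-loop mean squares, independently of
    the implementation."""
    x = [row for row in matrix]
    n, k = len(x), len(x[0])
    grand = sum(sum(r) for r in x) / (n * k)
    row_means = [sum(r) / k for r in x]
    col_means = [sum(x[i][j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((m - grand) ** 2 for m in row_means)
    ssc = n * sum((m - grand) ** 2 for m in col_means)
    sst = sum((x[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def test_icc_identical_columns_is_one():
    assert icc_absolute_agreement([[1, 1], [2, 2], [3, 3]]) == pytest.approx(1.0)


def test_icc_frozen_hand_example():
    # mean squares by hand: MSR=40/3, MSC=2, MSE=0 -> ICC = 40/43
    assert icc_absolute_agreement([[1, 2], [3, 4], [5, 6], [7, 8]]) == pytest.approx(40 / 43)


def test_icc_matches_anova_oracle_on_random_matrices():
    rng = np.random.default_rng(2024)
    for _ in range(300):
        n = int(rng.integers(3, 21))
        k = int(rng.integers(2, 5))
        m = rng.normal(size=(n, k)) + 1.5 * rng.normal(size=(n, 1))
        assert icc_absolute_agreement(m) == pytest.approx(
            anova_icc_oracle(m.tolist()), abs=1e-9
        )


def test_icc_matches_pingouin():
    import pandas as pd
    import pingouin as pg

    rng = np.random.default_rng(7)
    for _ in range(20):
        n = int(rng.integers(4, 15))
        m = rng.normal(size=(n, 2)) + rng.normal(size=(n, 1))
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(n), 2),
                "raters": np.tile(np.arange(2), n),
                "ratings": m.ravel(),
            }
        )
        ref = pg.intraclass_corr(df, targets="targets", raters="raters", ratings="ratings")
        expected = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert icc_absolute_agreement(m) == pytest.approx(expected, abs=1e-9)


def test_icc_never_exceeds_one():
    rng = np.random.default_rng(5)
    for _ in range(100):
        m = rng.normal(size=(int(rng.integers(3, 12)), 2))
        icc = icc_absolute_agreement(m)
        assert icc <= 1.0 + 1e-12


def test_icc_undefined_cases():
    assert icc_absolute_agreement([[1, 2], [3, 4]]) is None  # n < 3
    assert icc_absolute_agreement([[2, 2], [2, 2], [2, 2]]) is None  # zero variance


@pytest.mark.parametrize(
    "icc,band",
    [(0.3, "poor"), (0.6, "moderate"), (0.8, "good"), (0.93, "excellent")],
)
def test_reliability_bands(icc, band):
    assert icc_reliability_band(icc) == band


# ---------------------------------------------------------------------------
# Accuracy, confusion, aggregation
# ---------------------------------------------------------------------------


def test_exact_match_accuracy_zero():
    n, pct = exact_match_accuracy(["a"] * 5, ["b"] * 5)
    assert (n, pct) == (0, 0.0)


def test_accuracy_scale_invariant_under_duplication():
    preds = ["a", "b", "a", "c"]
    refs = ["a", "b", "b", "c"]
    _, pct = exact_match_accuracy(preds, refs)
    _, pct2 = exact_match_accuracy(preds * 3, refs * 3)
    assert pct == pct2


def test_confusion_matrix_diagonal_and_error_count():
    labels = ["a", "b", "c"]
    perfect = confusion_matrix(["a", "b", "c"], ["a", "b", "c"], labels)
    assert (np.diag(perfect.values) == 1).all()
    preds = ["a", "b", "b", "c", "unparseable"]
    refs = ["a", "b", "c", "c", "a"]
    cm = confusion_matrix(preds, refs, labels)
    assert cm.values.sum() == 5
    trace = sum(cm.loc[l, l] for l in labels)
    assert len(refs) - trace == 2


def test_median_iqr_convention():
    assert aggregate_median_iqr([0.80, 0.90, 0.95])[0] == pytest.approx(0.90)
    med, q1, q3 = aggregate_median_iqr([1, 2, 3, 4])
    assert (med, q1, q3) == (2.5, 1.75, 3.25)
    assert aggregate_median_iqr([0.7]) == (0.7, 0.7, 0.7)


def test_round_half_up():
    assert round_half_up(86.505, 2) == 86.51
    assert round_half_up(0.125, 2) == 0.13
    assert round_half_up(88.545, 1) == 88.5


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


def test_bootstrap_constant_metric_degenerate_ci():
    low, high = bootstrap_ci(lambda idx: 0.42, n_cases=50, B=200, seed=1)
    assert (low, high) == (0.42, 0.42)


def test_bootstrap_seed_deterministic():
    data = np.random.default_rng(3).normal(size=80)
    fn = lambda idx: float(np.mean(data[idx]))  # noqa: E731
    assert bootstrap_ci(fn, 80, B=500, seed=9) == bootstrap_ci(fn, 80, B=500, seed=9)
    assert bootstrap_ci(fn, 80, B=500, seed=9) != bootstrap_ci(fn, 80, B=500, seed=10)


def test_bootstrap_width_close_to_normal_approximation():
    """Accuracy CI width within 20% of the analytic binomial width."""
    rng = np.random.default_rng(0)
    n = 200
    correct = (rng.random(n) < 0.7).astype(float)
    fn = lambda idx: float(np.mean(correct[idx]))  # noqa: E731
    low, high = bootstrap_ci(fn, n, B=1000, seed=4)
    p = correct.mean()
    analytic = 2 * 1.96 * np.sqrt(p * (1 - p) / n)
    assert abs((high - low) - analytic) / analytic < 0.2


def test_bootstrap_redraws_undefined_resamples():
    calls = {"n": 0}

    def sometimes_undefined(idx):
        calls["n"] += 1
        return None if calls["n"] % 3 == 0 else float(len(idx))

    low, high = bootstrap_ci(sometimes_undefined, n_cases=10, B=100, seed=2)
    assert low == high == 10.0
    assert calls["n"] > 100  # undefined draws were redrawn


def test_bootstrap_ci_contains_point_estimate_calibration():
    """Percentile CIs contain the point estimate for >= 95% of random
    datasets (smoke calibration, seeded)."""
    rng = np.random.default_rng(12)
    hits = 0
    trials = 100
    for _ in range(trials):
        data = rng.normal(size=40)
        point = float(np.mean(data))
        low, high = bootstrap_ci(
            lambda idx, d=data: float(np.mean(d[idx])), 40, B=300,
            seed=int(rng.integers(0, 2**31)),
        )
        hits += low <= point <= high
    assert hits >= 95


# ---------------------------------------------------------------------------
# Extraction report assembly
# ---------------------------------------------------------------------------


def test_perfect_extraction_gives_unit_f1_and_icc(small_bundles, dicts_en):
    from hepadecide import gold_to_structured

    golds = [b.gold for b in small_bundles]
    records = [gold_to_structured(g) for g in golds]
    report = evaluate_extraction(records, golds, B=100, seed=0)
    assert report.concept_f1_summary[0] == 1.0
    for m in report.per_numeric_icc.values():
        assert m.value == pytest.approx(1.0)
        assert m.band == "excellent"
    for m in report.per_concept_f1.values():
        assert m.ci_low <= m.value <= m.ci_high


def test_noise_strictly_degrades_scores(small_bundles, dicts_en, exemplars):
    """Parameter-recovery monotonicity: increasing mock noise strictly
    decreases median F1 and median ICC."""
    from hepadecide import NoisyExtractionBackend, llm_extract

    golds = [b.gold for b in small_bundles]
    rendered = {b.render.case_id: b.render.rendered_fields for b in small_bundles}
    medians_f1, medians_icc = [], []
    for drop, flip in ((0.0, 0.0), (0.2, 0.2), (0.5, 0.5)):
        backend = NoisyExtractionBackend(dicts_en, drop_prob=drop, flip_prob=flip, seed=3)
        records = [llm_extract(b.note, backend, exemplars) for b in small_bundles]
        report = evaluate_extraction(records, golds, rendered=rendered, B=50, seed=1)
        medians_f1.append(report.concept_f1_summary[0])
        medians_icc.append(report.numeric_icc_summary[0])
    assert medians_f1[0] == 1.0 and medians_icc[0] == pytest.approx(1.0)
    assert medians_f1[0] > medians_f1[1] > medians_f1[2]
    assert medians_icc[0] > medians_icc[1] > medians_icc[2]
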