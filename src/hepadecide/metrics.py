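"""Scoring protocol: agreement statistics for extraction and decisions.

Categorical concepts are scored with the F1 of the "present" class
(``not_reported`` and unparseable outputs count as incorrect, never as
present). Numerical parameters are scored two ways, reported side by side:
agreement as exact match up to the first decimal place, and reliability as
the single-measure two-way intraclass correlation for absolute agreement,
ICC(A,1). Decisions are scored as exact-match accuracy with confusion
matrices. Confidence intervals come from case-level bootstrap percentile
resampling (1,000 replicates, 2.5th/97.5th percentiles).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .records import (
    ALL_FIELDS,
    CONCEPT_FIELDS,
    NOT_REPORTED,
    NUMERIC_FIELDS,
    PRESENT,
    GoldRecord,
    StructuredRecord,
    gold_to_structured,
)

logger = logging.getLogger(__name__)

BOOTSTRAP_REPLICATES = 1000


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (the convention for all report percentages)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Per-item metrics
# ---------------------------------------------------------------------------


def f1_categorical(preds: Sequence[str], refs: Sequence[str]) -> float:
    """F1 of the "present" class.

    ``not_reported`` (or any non-"present" output) is never credited as
    present: it contributes a false negative when the reference is present.
    Returns 0.0 when precision + recall is zero.
    """
    if len(preds) != len(refs):
        raise ValueError(f"length mismatch: {len(preds)} vs {len(refs)}")
    tp = fp = fn = 0
    for p, r in zip(preds, refs):
        if p == PRESENT and r == PRESENT:
            tp += 1
        elif p == PRESENT:
            fp += 1
        elif r == PRESENT:
            fn += 1
    denom = 2 * tp + fp + fn
    return (2 * tp / denom) if denom else 0.0


def numeric_match(pred, ref) -> bool:
    """Exact match up to the first decimal place.

    Both values are half-up rounded to one decimal before comparison; any
    residual difference is incorrect. A ``not_reported`` prediction never
    matches a reported reference; two ``not_reported`` values agree.
    """
    pred_nr = pred == NOT_REPORTED or pred is None
    ref_nr = ref == NOT_REPORTED or ref is None
    if pred_nr or ref_nr:
        return pred_nr and ref_nr
    return round_half_up(float(pred), 1) == round_half_up(float(ref), 1)


def icc_absolute_agreement(paired_values: Sequence[Sequence[float]]) -> Optional[float]:
    """Single-measure two-way ICC for absolute agreement, ICC(A,1).

    From the two-way ANOVA decomposition with n subjects and k raters::

        ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    where MSR, MSC and MSE are the between-subject, between-rater and
    residual mean squares. Returns ``None`` (not available) for fewer than
    3 complete pairs or zero total variance.
    """
    x = np.asarray(paired_values, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need an n x k matrix with k >= 2 raters")
    x = x[~np.isnan(x).any(axis=1)]
    n, k = x.shape
    if n < 3:
        return None
    grand = x.mean()
    ss_total = float(((x - grand) ** 2).sum())
    if ss_total == 0.0:
        return None
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0.0:
        return None
    return (msr - mse) / denom


def icc_reliability_band(icc: float) -> str:
    """Reliability interpretation: <0.50 poor, 0.50-0.75 moderate,
    0.75-0.90 good, >0.90 excellent."""
    if icc < 0.50:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc <= 0.90:
        return "good"
    return "excellent"


def exact_match_accuracy(preds: Sequence, refs: Sequence) -> Tuple[int, float]:
    """(number correct, percent) under exact label matching; percentages are
    half-up rounded to two decimals."""
    if len(preds) != len(refs):
        raise ValueError(f"length mismatch: {len(preds)} vs {len(refs)}")
    if not refs:
        raise ValueError("empty inputs")
    n_correct = sum(1 for p, r in zip(preds, refs) if p == r)
    return n_correct, round_half_up(100.0 * n_correct / len(refs), 2)


def confusion_matrix(
    preds: Sequence[str], refs: Sequence[str], label_set: Sequence[str]
) -> pd.DataFrame:
    """Reference-by-prediction count matrix over a fixed label set.

    Predictions outside the label set (e.g. the unparseable sentinel) are
    kept in an extra column so every case is accounted for.
    """
    labels = list(label_set)
    extra = sorted({p for p in preds if p not in labels})
    cols = labels + extra
    m = _sk_confusion(refs, preds, labels=cols)
    df = pd.DataFrame(m, index=cols, columns=cols)
    return df.loc[labels, cols]  # references are always canonical


def aggregate_median_iqr(values: Sequence[float]) -> Tuple[float, float, float]:
    """(median, Q1, Q3) with linear-interpolation (type-7) quantiles."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("no values to aggregate")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return float(med), float(q1), float(q3)


def bootstrap_ci(
    metric_fn: Callable[[Sequence[int]], Optional[float]],
    n_cases: int,
    B: int = BOOTSTRAP_REPLICATES,
    seed: int = 0,
    ci: float = 0.95,
) -> Tuple[float, float]:
    """Case-level bootstrap percentile CI.

    ``metric_fn`` receives an index array (a resample of case indices with
    replacement) and returns the metric or ``None`` when undefined on that
    resample; undefined resamples are redrawn and counted. Deterministic
    under the seed.
    """
    if n_cases < 1:
        raise ValueError("cannot bootstrap an empty dataset")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(5,)))
    stats: List[float] = []
    redrawn = 0
    attempts = 0
    max_attempts = 20 * B
    while len(stats) < B and attempts < max_attempts:
        attempts += 1
        idx = rng.integers(0, n_cases, size=n_cases)
        value = metric_fn(idx)
        if value is None or (isinstance(value, float) and np.isnan(value)):
            redrawn += 1
            continue
        stats.append(float(value))
    if redrawn:
        logger.info("bootstrap redrew %d undefined resamples", redrawn)
    if not stats:
        return (float("nan"), float("nan"))
    alpha = 100.0 * (1.0 - ci) / 2.0
    low, high = np.percentile(np.asarray(stats), [alpha, 100.0 - alpha])
    return float(low), float(high)


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------


@dataclass
class MetricWithCI:
    value: Optional[float]
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    band: Optional[str] = None
    n: int = 0

    def as_dict(self) -> dict:
        return {
            "value": self.value,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "band": self.band,
            "n": self.n,
        }


@dataclass
class EvalReport:
    """Per-item and aggregated extraction metrics."""

    per_concept_f1: Dict[str, MetricWithCI]
    per_numeric_icc: Dict[str, MetricWithCI]
    per_numeric_match_rate: Dict[str, MetricWithCI]
    concept_f1_summary: Tuple[float, float, float]
    numeric_icc_summary: Tuple[float, float, float]

    def as_dict(self) -> dict:
        return {
            "per_concept_f1": {k: v.as_dict() for k, v in self.per_concept_f1.items()},
            "per_numeric_icc": {k: v.as_dict() for k, v in self.per_numeric_icc.items()},
            "per_numeric_match_rate": {
                k: v.as_dict() for k, v in self.per_numeric_match_rate.items()
            },
            "concept_f1_median_q1_q3": list(self.concept_f1_summary),
            "numeric_icc_median_q1_q3": list(self.numeric_icc_summary),
        }

    def tables(self) -> pd.DataFrame:
        rows = []
        for name, m in self.per_concept_f1.items():
            rows.append(("concept", name, "F1", m.value, m.ci_low, m.ci_high, m.n))
        for name, m in self.per_numeric_icc.items():
            rows.append(("numeric", name, "ICC", m.value, m.ci_low, m.ci_high, m.n))
        for name, m in self.per_numeric_match_rate.items():
            rows.append(("numeric", name, "exact_match_rate", m.value, m.ci_low,
                         m.ci_high, m.n))
        return pd.DataFrame(
            rows, columns=["domain", "item", "metric", "value", "ci_low", "ci_high", "n"]
        )


RenderedMask = Optional[Dict[str, set]]


def _gold_expectations(golds: Sequence[GoldRecord]) -> List[StructuredRecord]:
    return [gold_to_structured(g) for g in golds]


def evaluate_extraction(
    records: Sequence[StructuredRecord],
    golds: Sequence[GoldRecord],
    rendered: RenderedMask = None,
    B: int = BOOTSTRAP_REPLICATES,
    seed: int = 0,
) -> EvalReport:
    """Score extracted records against gold profiles.

    ``rendered`` (case_id -> set of field names actually written into the
    note) restricts each field's case set to the cases where the field was
    rendered; fields a note never mentioned are otherwise unknowable.
    ICC uses complete raw-value pairs; pairs with a missing side are
    excluded from ICC but scored incorrect in the exact-match rate.
    """
    if len(records) != len(golds):
        raise ValueError("records and golds must align")
    refs = _gold_expectations(golds)

    def included(field_name: str) -> List[int]:
        if rendered is None:
            return list(range(len(golds)))
        return [
            i for i, g in enumerate(golds)
            if field_name in rendered.get(g.case_id, set())
        ]

    per_f1: Dict[str, MetricWithCI] = {}
    for name in CONCEPT_FIELDS:
        idx = included(name)
        preds = [records[i].get(name) for i in idx]
        target = [refs[i].get(name) for i in idx]
        if not idx:
            per_f1[name] = MetricWithCI(value=None, n=0)
            continue
        point = f1_categorical(preds, target)
        low, high = bootstrap_ci(
            lambda sample, p=preds, t=target: f1_categorical(
                [p[j] for j in sample], [t[j] for j in sample]
            ),
            n_cases=len(idx),
            B=B,
            seed=seed + 1,
        )
        per_f1[name] = MetricWithCI(point, low, high, n=len(idx))

    per_icc: Dict[str, MetricWithCI] = {}
    per_match: Dict[str, MetricWithCI] = {}
    for name in NUMERIC_FIELDS:
        idx = included(name)
        preds = [records[i].get(name) for i in idx]
        target = [refs[i].get(name) for i in idx]
        if not idx:
            per_icc[name] = MetricWithCI(value=None, n=0)
            per_match[name] = MetricWithCI(value=None, n=0)
            continue
        matches = [numeric_match(p, t) for p, t in zip(preds, target)]
        rate = 100.0 * sum(matches) / len(matches)
        mlow, mhigh = bootstrap_ci(
            lambda sample, m=matches: 100.0 * sum(m[j] for j in sample) / len(sample),
            n_cases=len(idx),
            B=B,
            seed=seed + 2,
        )
        per_match[name] = MetricWithCI(round_half_up(rate, 2), mlow, mhigh, n=len(idx))

        pairs = [
            (float(p), float(t))
            for p, t in zip(preds, target)
            if p != NOT_REPORTED and t != NOT_REPORTED
        ]
        if len(pairs) < 3:
            per_icc[name] = MetricWithCI(value=None, n=len(pairs))
            continue
        point = icc_absolute_agreement(pairs)

        def icc_on(sample, pp=pairs):
            return icc_absolute_agreement([pp[j] for j in sample])

        low, high = bootstrap_ci(icc_on, n_cases=len(pairs), B=B, seed=seed + 3)
        band = icc_reliability_band(point) if point is not None else None
        per_icc[name] = MetricWithCI(point, low, high, band=band, n=len(pairs))

    f1_values = [m.value for m in per_f1.values() if m.value is not None]
    icc_values = [m.value for m in per_icc.values() if m.value is not None]
    return EvalReport(
        per_concept_f1=per_f1,
        per_numeric_icc=per_icc,
        per_numeric_match_rate=per_match,
        concept_f1_summary=aggregate_median_iqr(f1_values) if f1_values else (float("nan"),) * 3,
        numeric_icc_summary=aggregate_median_iqr(icc_values) if icc_values else (float("nan"),) * 3,
    )


def decision_accuracy(
    rows: Sequence[dict],
    golds: Dict[str, GoldRecord],
) -> pd.DataFrame:
    """Exact-match accuracy per (backend, configuration, task) from an
    ablation decision log, with unparseable outputs scored incorrect."""
    frame = pd.DataFrame(list(rows))
    out = []
    for (backend, prompting, form), group in frame.groupby(
        ["backend", "prompting", "input_form"]
    ):
        for task in ("treatment", "complexity", "mdt"):
            refs = [getattr(golds[cid].reference_decision, task) for cid in group["case_id"]]
            n_correct, pct = exact_match_accuracy(group[task].tolist(), refs)
            out.append(
                {
                    "backend": backend,
                    "prompting": prompting,
                    "input_form": form,
                    "task": task,
                    "n_correct": n_correct,
                    "n_total": len(refs),
                    "accuracy_pct": pct,
                }
            )
    return pd.DataFrame(out)
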