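# Methods

`hepadecide` is a testbed for a two-stage clinical decision-support pipeline
for hepatocellular carcinoma (HCC): (1) structured extraction of
decision-relevant parameters from narrative notes, and (2) generation of
three management decisions — treatment allocation, clinical complexity
grade, and multidisciplinary-team (MDT) referral — from the case
representation, optionally conditioned on few-shot exemplars and retrieved
guideline evidence. Because real HCC cohorts and large model weights cannot
ship with a library, every stage is exercisable end to end on synthetic
notes with deterministic mock generation backends; real models attach
through the same backend protocol.

## The extraction targets

Twelve parameters drive the decisions:

* six tri-state **clinical concepts** (`present` / `absent` /
  `not_reported`): vascular invasion, severe comorbidities, metastatic
  disease, previous HCC treatment, complete response to the last treatment,
  esophageal varices;
* six **numerical parameters**: AFP (ng/ml), serum albumin (g/dl), ECOG
  performance status (0–4), Child-Pugh score (5–15), MELD score (6–40),
  maximum nodule diameter (mm).

`StructuredRecord` holds these plus per-field provenance (`regex`, `llm`,
`fallback_regex`), and its canonical 12-line `Field: value` rendering is the
"structured note" fed to the decision stage.

## Regex extraction

Concepts are matched as contiguous token sequences from per-language term
dictionaries (bundled for English and Italian as user-editable YAML; the
lexicons are curated for common report phrasings and make no claim of
completeness). Negation is a window heuristic: a negation phrase within
**three word tokens** on either side of the matched span flips the mention
to `absent`. Numerical choices that the window rule leaves open, fixed here:

* the window counts word tokens only (punctuation is never tokenized) and
  stops at sentence boundaries (`.`, `;`, `:`, newline);
* distance is measured from the match *span*, not from a single keyword
  token;
* any non-negated mention wins over negated restatements (clinical notes
  restate findings; affirmation dominates).

Numeric parameters take the numeric token nearest to a keyword marker within
the same sentence (maximum gap four tokens); ties prefer the value
*following* the keyword. Number parsing accepts both decimal marks and
strips grouped thousands separators ("1.204,5" → 1204.5); a single
separator followed by exactly three digits in groups is read as a thousands
separator, otherwise as a decimal mark. Child-Pugh class–score compounds
("B7") resolve to the score. Extracted values outside the parameter's
physiologic domain (e.g. ECOG 9) degrade to `not_reported` rather than
polluting downstream stages.

The nodule diameter is special-cased: paragraphs containing an imaging
keyword and a four-digit year are treated as dated imaging sections; only
the section with the **most recent year** (ties: latest by document
position) is searched for dimensional mentions, and the maximum value is
returned in millimetres (cm × 10). Stale measurements in older sections are
thereby ignored.

## LLM extraction and the hybrid pipeline

Extraction prompts have a fixed structure: task specification listing the 12
parameters and formats, exactly **ten** worked report→extraction exemplar
pairs, explicit step-by-step instructions with a strict `Field: value`
output schema, then the target report. Generation uses deterministic
settings (temperature 0, max 50 tokens); decision generation uses
temperature 0.8 with max 500 tokens and a recorded seed. The output parser
is total: missing, malformed, or out-of-domain fields degrade to
`not_reported` (logged), never an exception. Whether a model answered
"not reported" explicitly or emitted something unparseable is
indistinguishable in scores by design; the distinction survives only in
logs.

The hybrid extractor is LLM-primary with **per-field** regex fallback: a
field the model reports is kept verbatim (an optional audit mode logs regex
disagreements without changing output); only fields the model leaves
unreported trigger the regex backup. Hence hybrid coverage is guaranteed ≥
LLM-only coverage, and equals regex coverage only on the fallback fields.

Two mock backends make the pipeline testable without weights: an **oracle**
(applies the regex extractor to the report embedded in the prompt, or reads
a structured block off directly, as a competent model would) and a **noisy**
mock (seeded per-field drop/flip noise on top of the oracle, a pure function
of seed and prompt, so ablation deltas are measurable and reproducible).

## Retrieval

Reference documents are chunked at blank-line paragraph boundaries;
paragraphs under five words merge forward so chunks stay self-contained.
The bundled embedder is a deterministic token-hashing bag-of-words model
(MD5 bucket hashing, 256 dimensions, L2-normalized) — any embedder exposing
`embed(texts)` can replace it, e.g. a sentence-transformer wrapper.
Similarity search is an exact cosine scan (reference corpora here are a few
documents, so approximate indexes would add dependencies without benefit);
the top **five chunks per reference document** (configurable) are retrieved
with the full case input as the query, the same representation the decision
prompt uses. Ties, including float-noise near-ties, break deterministically
by (doc id, chunk index) after rounding similarity to 1e-12.

The two bundled reference documents are *synthetic fixtures* written for
this package (real guideline texts are licensed); they play the structural
role of a clinical practice guideline and a treatment-hierarchy review, and
users should point the configuration at their own texts.

## Decision stage and the ablation grid

Six configurations cross prompting ∈ {zero_shot, few_shot, few_shot_rag}
with input form ∈ {unstructured raw note, structured 12-field block}.
Few-shot exemplars are ten cases sampled without replacement (seeded) and
excluded from evaluation in every configuration. The output grammar is
enforced by instruction ("exactly three labeled lines"); the parser maps
free-text variants to canonical categories through a synonym table (TACE →
transarterial treatment, trapianto → liver transplantation, ...) and scores
anything unmappable as the `unparseable` sentinel, incorrect on all three
tasks.

By default the structured case input is derived from the gold record, which
isolates decision generation from extraction errors (the intended use when
measuring prompting effects); callers can supply extracted records instead
to measure compounded two-stage error.

## The synthetic cohort

The generator emulates a tertiary-referral HCC decision cohort: mean age
71.2 ± 10.6 years, 73.3% male, treatment mix {transplantation 4.1%,
resection 8.4%, ablation 8.6%, transarterial 10.0%, systemic 30.9%, best
supportive care 19.4%, follow-up 18.6%} and complexity mix {low 23.1%,
moderate 55.6%, high 21.3%}. A treatment category and complexity grade are
sampled from these marginals; a clinical profile consistent with both is
then constructed (category-specific structural attributes, plus free
findings and three orthogonal "complexity knobs" — AFP > 400 ng/ml,
MELD ≥ 15, albumin < 2.8 g/dl — that steer the borderline-criteria score
without touching the treatment rules) and verified against the rule table.
`negation_rate` (default 0.3) is the probability that a free binary finding
is negative — negative findings render as negated mentions within the
three-token window; `missingness_rate` (default 0.1) independently omits
each parameter from the text. Notes carry one to three dated imaging
sections; only the most recent holds the gold diameter, older sections carry
decoy values differing by ≥ 5 mm so recency failures are detectable. The
generator records exactly which fields it rendered and which concepts it
negated, giving the evaluation stage an oracle for "fields actually
rendered". English and Italian template sets are provided; Italian uses
comma decimals and grouped thousands.

What the generator does **not** emulate: free-order narrative style,
abbreviation noise, OCR artifacts, contradictory restatements, tabular lab
panels, or institution-specific boilerplate. Perfect closed-loop scores on
this corpus therefore demonstrate the pipeline's internal consistency, not
expected performance on real notes.

### The reference-decision rule table

Real-world reference decisions are made by clinicians; the synthetic
corpus needs a deterministic, hepatology-plausible stand-in, documented in
`hepadecide/rules.py` (first match wins): complete response with no
measurable disease → follow-up; ECOG ≥ 3 → best supportive care; vascular
invasion or metastases with preserved liver function → systemic therapy;
lesion ≤ 50 mm with decompensation (Child-Pugh 7–12) or portal hypertension
and ECOG ≤ 1 → transplantation; compensated single-lesion disease without
portal hypertension → resection; ≤ 30 mm with ECOG 2 → ablation; remaining
liver-confined disease with preserved function → transarterial treatment;
otherwise best supportive care. Complexity is an additive
borderline-criteria score (low ≤ 1, moderate 2–3, high ≥ 4); MDT referral
covers every transplant, borderline resections, and high-complexity active
treatments. Two deliberate properties:

* the table is keyed **only to the 12 extraction targets** (diameter stands
  in for tumour burden), so a faithfully extracted structured note always
  carries the determinants of its own reference decision — this is what
  makes closed-loop decision tests well-posed;
* it is a total function, including on records with `not_reported` fields
  (conservative defaults: ECOG 1, Child-Pugh 6, MELD 10, AFP 0, albumin
  3.5), verified by exhaustive enumeration over a discretized profile grid.

The MDT rule in particular is an artifact construct, not a reconstruction of
any institutional criteria.

## Scoring protocol

* **Concepts**: F1 of the `present` class per concept; `not_reported` and
  unparseable outputs are incorrect and never count as present; F1 = 0 when
  precision + recall = 0.
* **Numerics**: two complementary views, reported side by side. Agreement =
  exact match after half-up rounding to the first decimal (two
  `not_reported` sides agree; one does not). Reliability = single-measure
  two-way ICC for absolute agreement, ICC(A,1) = (MSR − MSE) / (MSR +
  (k−1)MSE + k(MSC − MSE)/n), computed from scratch and cross-checked in
  tests against an explicit-loop ANOVA oracle and pingouin to 1e-9; bands
  < 0.50 poor, 0.50–0.75 moderate, 0.75–0.90 good, > 0.90 excellent.
  Pairs with a missing side are excluded from ICC but scored incorrect in
  the match rate; ICC is "not available" below three complete pairs or at
  zero total variance.
* **Decisions**: exact-match accuracy per task with confusion matrices
  (unparseable outputs kept in an extra column so every case is counted).
* **Aggregation**: median, Q1, Q3 across items within a domain, type-7
  (linear-interpolation) quantiles; percentages half-up rounded to the
  printed precision.
* **Uncertainty**: case-level bootstrap percentile intervals (B = 1000,
  2.5th/97.5th percentiles), resampling whole cases so within-case
  correlation is preserved; resamples on which a metric is undefined are
  redrawn and counted; fully seed-deterministic.

## Problem sizes and numerical conventions

The test suite and the acceptance script run the full pipeline at the
emulated cohort size (489 cases; 10 held out as few-shot exemplars) plus a
10,000-draw check of the cohort marginals; these sizes keep every
distributional check inside comfortable sampling bounds while the whole
suite completes in well under a minute. All randomness flows through
`numpy.random.SeedSequence` with explicit spawn keys, so every stage —
generation, mock noise, bootstrap — is byte-reproducible from a single
seed. Mock noise is keyed to a SHA-256 digest of the prompt, never to
Python's process-salted `hash`.

## Known limitations

* The term lexicons cover the bundled templates and common phrasings, not
  the breadth of real clinical language; they are data files precisely so
  deployments can extend them.
* The negation heuristic is windowed, not syntactic: long-range or scoped
  negation ("no evidence of either X or, for that matter, Y") will be
  missed beyond three tokens.
* The reference-decision rule ignores age, nodule count and treatment
  history nuances a tumour board would weigh; it exists to make the
  pipeline testable, not to encode clinical truth.
* Mock backends bound what the decision ablation can show: directions of
  effect and pipeline correctness, never any real model's accuracy.
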