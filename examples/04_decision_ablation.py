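"""Run the six-configuration decision ablation with mock backends.

Crosses prompting strategy (zero-shot, few-shot, few-shot+RAG) with input
form (raw note vs structured 12-field block). The oracle mock applies the
reference rule table to whatever the prompt gives it: on structured input it
is perfect by construction, on raw notes it loses the fields missing from
the text. The noisy mock corrupts decisions with a per-configuration error
rate (higher on unstructured input), producing the accuracy gradient the
ablation is designed to expose.
"""

from hepadecide import (
    ALL_CONFIGURATIONS,
    DecisionOracleBackend,
    GeneratorConfig,
    NoisyDecisionBackend,
    VectorIndex,
    bundled_reference_documents,
    decision_accuracy,
    generate_bundles,
    run_ablation,
)

bundles = generate_bundles(GeneratorConfig(n_cases=100, seed=11))
corpus = [(b.note, b.gold) for b in bundles]
golds = {b.gold.case_id: b.gold for b in bundles}

index = VectorIndex()
for doc_id, text in bundled_reference_documents().items():
    index.add_document(doc_id, text)

rows = run_ablation(
    corpus,
    [DecisionOracleBackend(), NoisyDecisionBackend(seed=11)],
    ALL_CONFIGURATIONS,
    index=index,
    seed=11,
)
accuracy = decision_accuracy(rows, golds)
table = accuracy.pivot_table(
    index=["backend", "task"], columns=["prompting", "input_form"],
    values="accuracy_pct",
)
print(table.to_string())
print(
    "\nEach cell is exact-match accuracy (%) against the reference decisions "
    "on the 90 evaluation cases (10 cases serve as few-shot exemplars). "
    "Structured input never hurts; retrieval plus few-shot helps most."
)
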