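"""Retrieve guideline evidence for a clinical case.

Chunks the two bundled synthetic reference documents at paragraph level,
embeds them with the deterministic hashing embedder, and retrieves the five
most similar chunks from each document for a structured case — exactly what
the retrieval-augmented decision prompts are fed.
"""

from hepadecide import (
    GeneratorConfig,
    VectorIndex,
    bundled_reference_documents,
    generate_case,
    gold_to_structured,
    render_structured_note,
)

index = VectorIndex()
for doc_id, text in bundled_reference_documents().items():
    n = index.add_document(doc_id, text)
    print(f"indexed {doc_id}: {n} paragraph chunks")

bundle = generate_case(GeneratorConfig(n_cases=1, seed=3), 0)
query = render_structured_note(gold_to_structured(bundle.gold))
print("\n=== query (structured case) ===")
print(query)

print("\n=== top-5 chunks per reference document (cosine similarity) ===")
for result in index.retrieve(query, k_per_doc=5):
    first_line = result.chunk.text.splitlines()[0][:70]
    print(f"{result.similarity:6.3f}  [{result.chunk.doc_id} #{result.chunk.chunk_index}] {first_line}")
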