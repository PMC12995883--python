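import pytest

from hepadecide import (
    GeneratorConfig,
    VectorIndex,
    bundled_reference_documents,
    generate_bundles,
    load_dictionaries,
    make_exemplars,
)


@pytest.fixture(scope="session")
def dicts_en():
    return load_dictionaries("en")


@pytest.fixture(scope="session")
def dicts_it():
    return load_dictionaries("it")


@pytest.fixture(scope="session")
def small_bundles():
    """60 English cases with the default cohort marginals, mixed negation
    and missingness."""
    return generate_bundles(GeneratorConfig(n_cases=60, seed=7))


@pytest.fixture(scope="session")
def small_corpus(small_bundles):
    return [(b.note, b.gold) for b in small_bundles]


@pytest.fixture(scope="session")
def exemplars():
    return make_exemplars(language="en", seed=12345)


@pytest.fixture(scope="session")
def guideline_index():
    index = VectorIndex()
    for doc_id, text in bundled_reference_documents().items():
        index.add_document(doc_id, text)
    return index
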