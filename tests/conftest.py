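import pytest

from itembank import (
    HashingBackend,
    NormalizationDictionaries,
    SyntheticSpec,
    clean_corpus,
    generate_anchor_terms,
    generate_corpus,
)


@pytest.fixture(scope="session")
def dicts():
    return NormalizationDictionaries.default()


@pytest.fixture(scope="session")
def backend():
    return HashingBackend()


@pytest.fixture(scope="session")
def small_world():
    """A cleaned 4-domain corpus with ground truth and anchors."""
    spec = SyntheticSpec(n_domains=4, items_per_domain=25, noise_word_rate=0.1, seed=11)
    corpus, truth = generate_corpus(spec)
    cleaned = clean_corpus(corpus)
    anchors = generate_anchor_terms(truth, per_domain=1, seed=11)
    return cleaned, truth, anchors
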