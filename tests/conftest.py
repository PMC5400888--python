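import pytest

from stakeminer import (
    default_sentiment_lexicon,
    default_term_lexicon,
    generate_corpus,
    preprocess,
    preset,
)


@pytest.fixture(scope="session")
def term_lexicon():
    return default_term_lexicon()


@pytest.fixture(scope="session")
def sentiment_lexicon():
    return default_sentiment_lexicon()


@pytest.fixture(scope="session")
def tiny_bundle():
    """A small three-group synthetic corpus with gold labels."""
    corpus, gold = generate_corpus(preset("tiny", seed=11))
    return preprocess(corpus), gold


@pytest.fixture(scope="session")
def paperlike_bundle():
    corpus, gold = generate_corpus(preset("paperlike", seed=1))
    return preprocess(corpus), gold
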