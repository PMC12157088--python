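import numpy as np
import pytest

from lexner import pipeline as pl
from lexner import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def tiny_cfg():
    """A corpus small enough for sub-second training in unit tests."""
    return sd.SynthConfig(n_sentences=30, n_dev=10, n_test=10,
                          lexicon_size=12, entity_density=1.2,
                          min_len=6, max_len=10, seed=5)


@pytest.fixture(scope="session")
def tiny_corpus(tiny_cfg):
    lex = sd.generate_lexicon(tiny_cfg)
    corpus = sd.generate_corpus(tiny_cfg, lex)
    return tiny_cfg, lex, corpus


@pytest.fixture(scope="session")
def tiny_model_setup(tiny_corpus):
    cfg, lex, corpus = tiny_corpus
    vocab = pl.build_char_vocab(corpus.splits().values())
    cats = pl.corpus_categories(corpus.train)
    mc = pl.ModelConfig(d=16, h=2, T_rounds=1, depth=1, seed=3)
    return mc, lex, cats, vocab, corpus
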