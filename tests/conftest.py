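import numpy as np
import pytest
from hypothesis import settings

from deidseq.evaluation import train_on_corpus
from deidseq.synthetic import GeneratorConfig, generate_corpus

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_corpus():
    """60-document gold corpus shared by I/O and evaluation tests."""
    return generate_corpus(GeneratorConfig(seed=7, n_documents=60))


@pytest.fixture(scope="session")
def trained_tagger(small_corpus):
    """A small BiGRU-CRF fitted once and reused across tests."""
    return train_on_corpus(
        small_corpus,
        model="gru",
        decoder="crf",
        seed=7,
        epochs=6,
        patience=3,
        hidden=48,
        d_char=16,
        d_char_hidden=16,
        d_word=32,
    )
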