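import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from abbrex.corpus import Dialogue, GeneratorConfig, Turn, generate_synthetic_corpus
from abbrex.lm import train_ngram


@pytest.fixture(scope="session")
def small_corpus():
    return generate_synthetic_corpus(20, 7, GeneratorConfig(word_reuse_prob=0.6))


@pytest.fixture(scope="session")
def corpus_lm(small_corpus):
    """Trigram model trained on a disjoint corpus over the same grammar."""
    train = generate_synthetic_corpus(120, 1007, GeneratorConfig(word_reuse_prob=0.6))
    return train_ngram([t.text for d in train for t in d.turns], 3)


@pytest.fixture()
def toy_dialogue():
    return Dialogue(
        "toy-0",
        (
            Turn("A", "Been sitting all day. Work was just one meeting after another."),
            Turn("B", "Oh, I'm sorry."),
        ),
    )
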