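import pytest

from ocsrkit.corpus import generate_tiny_corpus
from ocsrkit.depiction import DepictionStyle, render_dataset
from ocsrkit.vocab import Vocabulary

# desk-scale rendering style: canvas equals the model input size so thin
# bond lines survive binarization
TINY_STYLE = DepictionStyle(
    canvas=64, bond_line_width=2.0, min_font_size=6, max_font_size=10,
    rotation_jitter=0.0,
)


@pytest.fixture(scope="session")
def tiny_records():
    return generate_tiny_corpus(6, seed=1)


@pytest.fixture(scope="session")
def tiny_vocab(tiny_records):
    return Vocabulary.from_corpus([r.deepsmiles for r in tiny_records])


@pytest.fixture(scope="session")
def tiny_max_len(tiny_records):
    return max(len(r.deepsmiles) for r in tiny_records) + 2


@pytest.fixture(scope="session")
def tiny_samples(tiny_records, tiny_vocab, tiny_max_len):
    samples, excluded = render_dataset(
        tiny_records, tiny_vocab, tiny_max_len, style=TINY_STYLE, seed=0,
        image_size=64,
    )
    assert not excluded
    return samples
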