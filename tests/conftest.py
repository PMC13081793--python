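import logging

import numpy as np
import pytest

from marinesed.fixtures import gen_corpus

logging.getLogger("marinesed.annotate").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def corpus():
    """Default fixture corpus: 4 classes, 12 segments each over 3 recordings."""
    return gen_corpus(n_per_class=12, n_recordings_per_class=3, seed=0)


@pytest.fixture(scope="session")
def class_map(corpus):
    return {name: i for i, name in enumerate(corpus.classes)}
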