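import numpy as np
import pytest

from itsfold.energy import default_model


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture(scope="session")
def random_short_sequences():
    """1,000 seeded random RNA sequences of length 5..14 (shared oracle set)."""
    rng = np.random.default_rng(20240915)
    seqs = []
    for _ in range(1000):
        n = int(rng.integers(5, 15))
        seqs.append("".join(rng.choice(list("ACGU"), size=n)))
    return seqs


@pytest.fixture(scope="session")
def folded_short_sequences(random_short_sequences, model):
    """MFE folds of the shared short-sequence set (computed once)."""
    from itsfold.fold import fold_mfe

    return [(s, fold_mfe(s, model)) for s in random_short_sequences]
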