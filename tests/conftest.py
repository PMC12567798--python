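import numpy as np
import pandas as pd
import pytest

from seqtox._aadata import ALPHABET
from seqtox.sequence_io import Dataset, ProteinRecord


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def random_sequences(rng):
    """100 random sequences of length 35-200 over the full alphabet."""
    seqs = []
    for i in range(100):
        L = int(rng.integers(35, 201))
        seqs.append("".join(rng.choice(list(ALPHABET), size=L)))
    return seqs


@pytest.fixture(scope="session")
def exhaustive_short_sequences():
    """Every sequence of length 1..10 over the reduced alphabet {A, C}."""
    out = []
    frontier = [""]
    for _ in range(10):
        frontier = [s + aa for s in frontier for aa in "AC"]
        out.extend(frontier)
    return out


def make_dataset(seqs, prefix="s", label="unlabelled"):
    return Dataset(
        [ProteinRecord(f"{prefix}{i}", s) for i, s in enumerate(seqs)], label=label
    )


@pytest.fixture
def toy_labelled_matrix():
    """Separable numeric matrix: 5 informative + 20 noise columns."""
    local = np.random.default_rng(777)
    n = 120
    y = np.array([0, 1] * (n // 2))
    info = local.normal(size=(n, 5)) + 1.5 * y[:, None]
    noise = local.normal(size=(n, 20))
    x = np.hstack([info, noise])
    cols = [f"info{i}" for i in range(5)] + [f"noise{i}" for i in range(20)]
    fm = pd.DataFrame(x, columns=cols, index=[f"r{i}" for i in range(n)])
    return fm, y
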