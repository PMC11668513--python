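import numpy as np
import pandas as pd
import pytest

from rdpa import QuantMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, groups_per_col, ids=None):
    """Helper: QuantMatrix from a 2-D list/array and per-column labels."""
    arr = np.asarray(values, dtype=float)
    cols = [f"S{i + 1}" for i in range(arr.shape[1])]
    ids = ids or [f"P{i + 1}" for i in range(arr.shape[0])]
    groups = dict(zip(cols, groups_per_col))
    return QuantMatrix(pd.DataFrame(arr, index=ids, columns=cols), groups)


@pytest.fixture
def small_proteome():
    return {
        "P1": "MKKRAAAKAKKDDEEDDEE",
        "P2": "ACDEFGHIKLMNPQRSTVWY",
        "P3": "GGGGGGGGGGGGGGGGGGGGGGGGGGGGGG",
    }


def random_protein(rng, length, kr_rate=0.25):
    """Random K/R-enriched sequence for motif-scanner stress tests."""
    other = list("ACDEFGHILMNPQSTVWYX")
    letters = np.where(
        rng.random(length) < kr_rate,
        rng.choice(["K", "R"], size=length),
        rng.choice(other, size=length),
    )
    return "".join(letters)
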