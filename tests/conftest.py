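import numpy as np
import pandas as pd
import pytest

from zfscreen.scanner import compile_pattern
from zfscreen.transcriptomics import CountMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def exact_pattern():
    return compile_pattern("GGTGATGGA", 0)


@pytest.fixture
def random_dna(rng):
    def make(length, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        return "".join(r.choice(list("ACGT"), size=length))

    return make


def null_count_matrix(seed, n_genes=2000, mu=100.0, phi=0.05, n_reps=3):
    """Two groups drawn from one NB law: the DE-test null scenario."""
    r = np.random.default_rng(seed)
    size = 1.0 / phi
    counts = pd.DataFrame(
        r.negative_binomial(size, size / (size + mu), size=(n_genes, 2 * n_reps)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{i}" for i in range(2 * n_reps)],
    )
    groups = pd.Series(
        ["A"] * n_reps + ["B"] * n_reps, index=counts.columns
    )
    return CountMatrix(counts=counts, groups=groups)
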