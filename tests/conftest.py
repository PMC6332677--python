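import numpy as np
import pandas as pd
import pytest

from reosig import ExpressionMatrix


def make_matrix(values, genes=None, samples=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


def random_matrix(rng, n_genes, n_samples, ties=False) -> ExpressionMatrix:
    x = rng.normal(8.0, 2.0, size=(n_genes, n_samples))
    if ties:
        x = np.round(x, 1)
    return make_matrix(x)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny():
    """3 genes totally ordered g0 > g1 > g2 in all 4 samples."""
    return make_matrix([[9, 9, 9, 9], [5, 5, 5, 5], [1, 1, 1, 1]])
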