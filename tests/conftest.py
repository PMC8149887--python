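import numpy as np
import pandas as pd
import pytest

from escompare.io import DETable, ExpressionMatrix, GeneSet


@pytest.fixture
def small_expr() -> ExpressionMatrix:
    """12 prenatal + 12 postnatal samples, 6 genes, no structure."""
    rng = np.random.default_rng(7)
    samples = [f"S{i:02d}" for i in range(24)]
    values = pd.DataFrame(rng.standard_normal((6, 24)),
                          index=[f"g{i}" for i in range(6)], columns=samples)
    ages = pd.Series(np.linspace(50, 5000, 24), index=samples)
    prenatal = pd.Series([True] * 12 + [False] * 12, index=samples)
    return ExpressionMatrix(values, ages, prenatal)


@pytest.fixture
def tiny_de_table() -> DETable:
    return DETable(pd.DataFrame({
        "gene": ["g1", "g2", "g3", "g4"],
        "log2fc": [1.0, -1.0, 0.0, 2.0],
        "pvalue": [0.5, 1.0, 0.1, 0.0],
        "padj": [0.6, 1.0, 0.2, 0.0],
    }))


def make_set(name, genes):
    return GeneSet.from_iterable(name, genes)
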