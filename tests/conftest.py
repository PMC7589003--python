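import numpy as np
import pandas as pd
import pytest

from ntcmetab import ExpressionMatrix, GeneSetCatalog


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def make_matrix(values, genes=None, cells=None, scale="counts"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(values, genes, cells, scale)


def make_annotation(cells, population="pop", genotype="WT", stage="E9.5"):
    n = len(cells)
    pops = [population] * n if isinstance(population, str) else list(population)
    genos = [genotype] * n if isinstance(genotype, str) else list(genotype)
    return pd.DataFrame(
        {
            "population": pops,
            "genotype": genos,
            "stage": stage,
            "total_umi": 0,
            "mito_fraction": 0.0,
        },
        index=pd.Index(cells, name="cell"),
    )


@pytest.fixture
def small_lognorm(rng):
    """20 genes x 50 cells of nonnegative 'log-normalized' values."""
    values = np.abs(rng.normal(1.0, 0.8, (20, 50)))
    values[rng.random((20, 50)) < 0.4] = 0.0
    return make_matrix(values, scale="lognorm")


@pytest.fixture
def two_set_catalog():
    return GeneSetCatalog({"setA": ["g0", "g1", "g2", "g3", "g4"], "setB": ["g5", "g6", "g7"]})
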