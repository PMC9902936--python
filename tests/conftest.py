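import numpy as np
import pandas as pd
import pytest

from clam.containers import ExpressionMatrix, InteractionDB, ModuleSet


def make_expression(values, genes=None, samples=None, dataset_id="toy"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i+1}" for i in range(values.shape[0])]
    samples = samples or [f"s{i+1}" for i in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), dataset_id=dataset_id
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_expression():
    """6 genes x 8 samples: two tight co-expression pairs plus noise genes."""
    gen = np.random.default_rng(7)
    base1 = gen.standard_normal(8)
    base2 = gen.standard_normal(8)
    rows = [
        base1 + 0.05 * gen.standard_normal(8),
        base1 + 0.05 * gen.standard_normal(8),
        base2 + 0.05 * gen.standard_normal(8),
        -base2 + 0.05 * gen.standard_normal(8),
        gen.standard_normal(8),
        gen.standard_normal(8),
    ]
    return make_expression(np.array(rows))


@pytest.fixture
def toy_interactions():
    return InteractionDB.from_edges(
        tf_edges=[("tfX", "g1"), ("tfX", "g2"), ("tfY", "g3")],
        mirna_edges=[("mir1", "g1"), ("mir1", "g4")],
        ppi_edges=[("g1", "g5"), ("g2", "g3")],
        pathways={"pw1": {"g1", "g2", "g6"}},
    )


@pytest.fixture
def toy_modules():
    return ModuleSet.from_dict(
        {"m1": {"a", "b", "c"}, "m2": {"d", "e"}}, outliers={"f"}
    )
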