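import numpy as np
import pandas as pd
import pytest

from cellvar.scvar import ExpressionMatrix
from cellvar.simulate import SimConfig, gen_sc_dataset


def make_expression(values: np.ndarray, populations, spikein=None) -> ExpressionMatrix:
    """Small ExpressionMatrix from a dense array and per-cell population labels."""
    n_feat, n_cells = values.shape
    feature_ids = [f"f{i}" for i in range(n_feat)]
    cell_ids = [f"c{i}" for i in range(n_cells)]
    vals = pd.DataFrame(values, index=feature_ids, columns=cell_ids, dtype=float)
    mapped = vals.sum(axis=0)
    cells = pd.DataFrame(
        {
            "population": list(populations),
            "total_reads": mapped.astype(int),
            "mapped_reads": mapped.astype(int),
            "spikein_reads": 0,
        },
        index=cell_ids,
    )
    features = pd.DataFrame(
        {"is_spikein": spikein if spikein is not None else [False] * n_feat},
        index=feature_ids,
    )
    return ExpressionMatrix(values=vals, cells=cells, features=features)


@pytest.fixture(scope="session")
def null_sc_dataset():
    """A k=1 (null) synthetic single-cell dataset."""
    return gen_sc_dataset(SimConfig(seed=7, inflation_factor=1.0))


@pytest.fixture(scope="session")
def inflated_sc_dataset():
    """A k=2 dataset with half the genes dispersion-inflated in HV."""
    return gen_sc_dataset(SimConfig(seed=7, inflation_factor=2.0))
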