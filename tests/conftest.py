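import numpy as np
import pandas as pd
import pytest

from spaxtalk import CellTable, ExpressionMatrix
from spaxtalk.synthetic_data import default_config, generate_dataset


def random_cells(
    n: int, seed: int, n_types: int = 4, n_fovs: int = 2, size: float = 200.0
) -> CellTable:
    """Small random cell table for oracle comparisons."""
    rng = np.random.default_rng(seed)
    fovs = rng.integers(0, n_fovs, n)
    df = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "x_um": rng.uniform(0, size, n) + fovs * size,
            "y_um": rng.uniform(0, size, n),
            "fov_id": [f"F{f}" for f in fovs],
            "cell_type": rng.choice([f"T{k}" for k in range(n_types)], n),
        }
    )
    return CellTable(df)


def random_expression(cells: CellTable, genes: list[str], seed: int) -> ExpressionMatrix:
    rng = np.random.default_rng(seed)
    values = rng.gamma(2.0, 2.0, size=(cells.n_cells, len(genes)))
    return ExpressionMatrix(values, pd.Index(genes), cells.cell_ids)


@pytest.fixture(scope="session")
def small_dataset():
    """One modest synthetic dataset shared across read-only tests."""
    cfg = default_config(n_fovs=2, cells_per_fov=300, seed=11)
    return generate_dataset(cfg)
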