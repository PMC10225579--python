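import numpy as np
import pandas as pd
import pytest

from dgcna import CountMatrix, SimulationParams, generate_dataset
from dgcna.simulate import star_pairs


@pytest.fixture(scope="session")
def two_module_dataset():
    """Two planted 50-gene modules (rho=0.85) plus 100 background genes."""
    params = SimulationParams(
        n_genes=200,
        n_samples_per_condition=(100, 100),
        module_sizes=[50, 50],
        within_module_cor=0.85,
        seed=3,
    )
    return generate_dataset(params)


@pytest.fixture(scope="session")
def planted_star_dataset():
    """Two stable modules plus three planted differential hub stars."""
    pairs = []
    for s in range(3):
        center = 80 + s * 7
        pairs += star_pairs(center, list(range(center + 1, center + 7)), 0.8, 0.0)
    params = SimulationParams(
        n_genes=220,
        n_samples_per_condition=(80, 80),
        module_sizes=[40, 40],
        within_module_cor=0.8,
        planted_pairs=pairs,
        seed=11,
    )
    return generate_dataset(params)


@pytest.fixture
def toy_counts():
    """Hand-sized count matrix with known row/column totals."""
    frame = pd.DataFrame(
        {
            "s1": [6, 1, 5, 0],
            "s2": [4, 1, 3, 0],
        },
        index=pd.Index(["gA", "gB", "gC", "gD"], name="gene_id"),
    )
    conditions = pd.Series(["cond1", "cond2"], index=["s1", "s2"], name="condition")
    return CountMatrix(frame, conditions)


def random_counts(n_genes: int, n_samples: int, seed: int) -> CountMatrix:
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(
        rng.integers(0, 200, size=(n_genes, n_samples)),
        index=pd.Index([f"g{i}" for i in range(n_genes)], name="gene_id"),
        columns=[f"s{j}" for j in range(n_samples)],
    )
    conditions = pd.Series(
        ["cond1" if j < n_samples // 2 else "cond2" for j in range(n_samples)],
        index=frame.columns,
        name="condition",
    )
    return CountMatrix(frame, conditions)
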