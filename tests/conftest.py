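import numpy as np
import pytest

from batsel import ExpressionMatrix, generate_dataset


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """4 genes x 6 samples with labels and one missing cell."""
    values = np.array([
        [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        [0.5, np.nan, 1.5, 2.5, 3.5, 4.5],
        [-1.0, -2.0, -3.0, 1.0, 2.0, 3.0],
        [0.0, 0.1, -0.1, 0.2, -0.2, 0.0],
    ])
    return ExpressionMatrix(
        values,
        gene_ids=["gA", "gB", "gC", "gD"],
        sample_ids=[f"s{i}" for i in range(6)],
        labels=np.array([0, 0, 0, 1, 1, 1]),
    )


@pytest.fixture
def planted_dataset():
    """Labelled matrix with a strong planted signal and block structure."""
    return generate_dataset(
        n_genes=60, n_samples=40, n_informative=5, blocks=(10, 10),
        rho=0.9, effect_size=2.0, noise_sd=1.0, seed=11,
    )
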