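import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracles.py importable

from icnet.data_io import ExpressionMatrix
from icnet.simulation import generate_scenario


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_scenario():
    """Compact noisy scenario shared by pipeline-level tests."""
    return generate_scenario(
        n_genes=10, n_tfs=3, n_proteins=8, l0=15, n_ppi_true=14,
        decoy_factor=1.5, seed=424242,
    )


@pytest.fixture(scope="session")
def clean_scenario():
    """Zero-noise scenario with candidate = true network, no sub-sampling."""
    return generate_scenario(
        n_genes=10, n_tfs=3, n_proteins=8, l0=21, n_ppi_true=14,
        decoy_factor=1.0, noise_sd_gene=0.0, noise_sd_protein=0.0,
        observe_stride=1, seed=77,
    )


@pytest.fixture
def log2_matrix():
    """4 nodes x 5 times log2-ratio matrix with one missing value."""
    values = np.array(
        [
            [0.1, 1.7, 0.3, -0.2, 0.0],
            [-2.0, 0.0, 0.0, 0.4, 0.2],
            [0.0, 0.0, 0.0, 0.0, 0.0],
            [1.0, np.nan, 2.0, 1.5, 0.5],
        ]
    )
    return ExpressionMatrix(["up", "down", "flat", "gappy"], [0, 5, 15, 30, 60], values)
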