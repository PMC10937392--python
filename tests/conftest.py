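import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from dccd import (
    ExpressionMatrix,
    default_bulk_signatures,
    simulate_bulk_cohort,
    simulate_dccd_cells,
    simulate_sc_counts,
)


@pytest.fixture(scope="session")
def bulk_signatures():
    return default_bulk_signatures()


@pytest.fixture(scope="session")
def sc_dataset():
    """Default-size single-cell simulation shared across marker tests."""
    return simulate_sc_counts(seed=0)


@pytest.fixture(scope="session")
def small_sc_dataset():
    return simulate_sc_counts(n_cells=400, n_genes=300, markers_per_cluster=20,
                              seed=1)


@pytest.fixture(scope="session")
def bulk_cohort(bulk_signatures):
    """n=120 four-subtype cohort at the default effect size and noise."""
    return simulate_bulk_cohort(n_samples=120, signatures=bulk_signatures,
                                signature_log2fc=2.0, noise_sd=1.0, seed=0)


@pytest.fixture(scope="session")
def gradient_cohort(bulk_signatures):
    """n=150 cohort with the planted IM2<->IM4 mixing gradient."""
    return simulate_bulk_cohort(n_samples=150, signatures=bulk_signatures,
                                dccd_gradient=True, seed=2)


@pytest.fixture(scope="session")
def cell_mixture():
    """10 samples of IM2/IM4 archetype cell mixtures."""
    return simulate_dccd_cells(seed=3)


@pytest.fixture
def tiny_expr():
    """6 genes x 3 samples, strictly decreasing in the first sample."""
    rng = np.random.default_rng(7)
    genes = [f"g{i}" for i in range(6)]
    vals = np.column_stack([
        np.arange(6, 0, -1, dtype=float),
        rng.normal(size=6),
        rng.normal(size=6),
    ])
    return ExpressionMatrix(
        pd.DataFrame(vals - vals.min() + 1.0, index=genes,
                     columns=["s1", "s2", "s3"]),
        "tpm")
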