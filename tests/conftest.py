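import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")

from icipipe.data_io import ExpressionMatrix
from icipipe.synthetic_data import SimulationConfig, make_reference_signature, simulate_cohort


@pytest.fixture
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_genes=400, n_samples=60, n_cell_types=5, n_clusters=2, seed=11
    )


@pytest.fixture
def small_cohort(small_config):
    """Expression, clinical, mutations and truth for a 60-sample cohort."""
    return simulate_cohort(small_config)


@pytest.fixture
def small_signature(small_config) -> ExpressionMatrix:
    return make_reference_signature(small_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_expression() -> ExpressionMatrix:
    values = pd.DataFrame(
        {
            "s1": [5.0, 5.0, 10.0],
            "s2": [1.0, 2.0, 3.0],
        },
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
    )
    return ExpressionMatrix(values, "FPKM")
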