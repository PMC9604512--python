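import numpy as np
import pandas as pd
import pytest

from pirs import (ExpressionMatrix, SimulationConfig, generate_cohort,
                  generate_reference_profiles)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A compact cohort: 10 per group, 6 cell types, 240 genes."""
    return SimulationConfig(n_per_group=10, n_genes=240, n_ifn_genes=15,
                            n_cytotoxic_genes=8, seed=7)


@pytest.fixture(scope="session")
def small_reference(small_config):
    return generate_reference_profiles(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_config, small_reference):
    return generate_cohort(small_config, small_reference)


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    data = pd.DataFrame(
        [[1.0, 2.0, 3.0], [4.0, 4.0, 4.0], [0.0, 5.0, 10.0]],
        index=["GENE1", "GENE2", "GENE3"],
        columns=["s1", "s2", "s3"],
    )
    return ExpressionMatrix(data, "log2")
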