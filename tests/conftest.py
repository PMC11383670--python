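import pandas as pd
import pytest

from decaptools import SimulationConfig, simulate


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_genes=400, library_depth=4e5, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate(small_config)


@pytest.fixture(scope="session")
def two_group_design() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": ["WT_rep1", "WT_rep2", "mut_rep1", "mut_rep2"],
            "genotype": ["WT", "WT", "mut", "mut"],
            "replicate": [1, 2, 1, 2],
        }
    )
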