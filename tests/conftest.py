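import numpy as np
import pandas as pd
import pytest

from trmshift import GeneratorConfig, default_profiles, sample_labels


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(
        n_cells_per_stratum={
            (g, c): 300 for g in ("WT", "TG") for c in ("brain", "meninges")
        },
        n_genes=200,
        baseline_mean=2.0,
        dispersion=2.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cells(profiles, small_config):
    return sample_labels(profiles, small_config)


@pytest.fixture
def toy_cells():
    """Six-cell brain stratum (3 WT, 3 TG) with two subsets."""
    return pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(6)],
            "group": ["WT", "WT", "WT", "TG", "TG", "TG"],
            "compartment": "brain",
            "subset": ["A", "A", "B", "A", "B", "B"],
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
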