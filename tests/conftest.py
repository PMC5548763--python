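import numpy as np
import pandas as pd
import pytest

from cardionet.datatypes import DEFAULT_TIMEPOINTS
from cardionet.simulate import ModuleSpec, SimulationConfig, simulate_dataset

TPS = list(DEFAULT_TIMEPOINTS)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def three_module_config():
    """Three planted TF modules with distinct temporal patterns, low noise."""
    return SimulationConfig(
        n_genes=200, n_tfs=80, n_mirnas=60,
        module_specs=[ModuleSpec(30, (2.5, 2.5, 2.5, 0.0, 0.0)),
                      ModuleSpec(25, (0.0, 0.0, 0.0, 2.5, 2.5)),
                      ModuleSpec(15, (-2.5, 0.0, 2.5, 0.0, -2.5))],
        frac_de_genes=0.1, de_effect=2.5, noise_sd=0.1, seed=11)


@pytest.fixture
def planted_dataset(three_module_config):
    return simulate_dataset(three_module_config)


@pytest.fixture
def null_config():
    return SimulationConfig(n_genes=150, n_tfs=20, n_mirnas=15,
                            frac_de_genes=0.0, de_effect=0.0, noise_sd=0.2,
                            n_tf_target_pairs=0, n_mirna_target_pairs=0,
                            seed=3)


def random_fold_changes(rng, n_features=200, timepoints=TPS):
    arr = rng.normal(size=(n_features, len(timepoints)))
    index = [f"f{i:04d}" for i in range(n_features)]
    return pd.DataFrame(arr, index=index, columns=timepoints)
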