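import numpy as np
import pytest

from magnet.config import ModelConfig
from magnet.simulate import SimulationSpec, make_toy_lr_db, simulate_dataset


@pytest.fixture(scope="session")
def fixture_150():
    """The standard 150-cell, 3-cluster, 60-gene planted-structure dataset."""
    spec = SimulationSpec(seed=7)
    ds, truth = simulate_dataset(spec)
    return ds, truth, make_toy_lr_db(spec), spec


@pytest.fixture(scope="session")
def small_ds():
    """A fast 40-cell dataset for unit tests of graph builders."""
    spec = SimulationSpec(n_cells=40, n_genes=30, n_lr_pairs=2,
                          n_markers_per_cluster=5, seed=3)
    ds, truth = simulate_dataset(spec)
    return ds, truth, make_toy_lr_db(spec), spec


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def fast_cfg():
    """A reduced config for training smoke tests."""
    return ModelConfig(epochs=15, patience=5, n_perm=25, hidden_dim=48,
                       k_genes=12, seed=3)
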