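import numpy as np
import pytest

from decidua_niche import synthetic


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale config small enough for per-test generation."""
    return synthetic.default_config(
        grid_rows=20, grid_cols=16, n_genes=300, n_sections_per_condition=1,
        signature_genes_per_subset=8, n_null_lr_pairs=10)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return synthetic.generate_dataset(small_config, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
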