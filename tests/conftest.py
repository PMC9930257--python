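import numpy as np
import pandas as pd
import pytest

import regulonscape as rs


@pytest.fixture(scope="session")
def default_dataset():
    """The default study conditions: 3 clusters x 200 cells, 2 planted
    regulons at fold 8, QC decoys included."""
    return rs.simulate_counts(rs.SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_norm(default_dataset):
    kept, _ = rs.qc_filter(default_dataset.counts, default_dataset.qc_params)
    return rs.normalize_log(kept)


@pytest.fixture(scope="session")
def default_labels(default_dataset, default_norm):
    return default_dataset.true_labels.loc[default_norm.index].to_numpy()


@pytest.fixture(scope="session")
def small_dataset():
    """A lighter dataset for structural tests."""
    return rs.simulate_counts(rs.SimConfig(seed=3, cells_per_cluster=40, n_genes=60))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def uniform_matrix():
    """Independent uniform expression, 200 cells x 6 genes (null data)."""
    gen = np.random.default_rng(42)
    return pd.DataFrame(
        gen.uniform(size=(200, 6)), columns=[f"g{i}" for i in range(6)],
        index=[f"c{i}" for i in range(200)],
    )
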