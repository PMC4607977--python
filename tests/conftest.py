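import numpy as np
import pandas as pd
import pytest

from coexval import ModulePartition, SyntheticSpec, make_modular_expression


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_dataset():
    """Three planted modules plus gray genes, small enough for fast tests."""
    spec = SyntheticSpec(
        n_samples=40, module_sizes=(12, 9, 6), module_strengths=(0.85, 0.8, 0.75),
        n_gray=40, seed=7,
    )
    return make_modular_expression(spec)


@pytest.fixture
def two_block_expression():
    """Two uncorrelated 5/3 gene blocks with high within-block correlation."""
    rng = np.random.default_rng(3)
    n = 24
    f1, f2 = rng.standard_normal(n), rng.standard_normal(n)
    rows = [0.95 * f1 + 0.31 * rng.standard_normal(n) for _ in range(5)]
    rows += [0.95 * f2 + 0.31 * rng.standard_normal(n) for _ in range(3)]
    return pd.DataFrame(rows, index=[f"g{i}" for i in range(8)])


def make_partition(mapping, gray_label="grey", min_size=3):
    labels = pd.Series(mapping, name="module")
    return ModulePartition(labels=labels, gray_label=gray_label, min_size=min_size)
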