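import numpy as np
import pytest

from otukit.synthetic import SyntheticSpec, generate_dataset
from otukit.tables_io import CountTable


@pytest.fixture
def tiny_table():
    return CountTable(
        ["s1", "s2", "s3", "s4"],
        ["t1", "t2", "t3"],
        np.array([[5, 3, 2], [1, 0, 9], [4, 4, 2], [0, 6, 4]]),
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One full-size synthetic dataset shared across read-only tests."""
    return generate_dataset(SyntheticSpec(seed=42))


@pytest.fixture(scope="session")
def small_spec():
    """Reduced-size spec for tests that generate many datasets."""
    return dict(n_caves=4, samples_per_cave_per_niche=2, n_taxa=150, depth=5000,
                n_blocks=2, block_size=6, n_gradient_taxa_per_factor=4)
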