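import numpy as np
import pytest

from scutpop.core_data import GenotypeTable
from scutpop import datasets


@pytest.fixture(scope="session")
def panel_dataset():
    """One nine-deme synthetic dataset (genotypes + sequences), fixed seed."""
    return datasets.example_dataset(seed=1)


@pytest.fixture(scope="session")
def taiwan_sites():
    return datasets.taiwan_sites()


@pytest.fixture
def two_deme_fixed():
    """Two demes fixed for different alleles at one locus."""
    return GenotypeTable(
        ["a1", "a2", "b1", "b2"],
        ["A", "A", "B", "B"],
        ["L1"],
        np.array([[[1, 1]], [[1, 1]], [[2, 2]], [[2, 2]]]),
    )


@pytest.fixture
def two_deme_half():
    """Deme A at p=(0.5, 0.5), deme B fixed: hand-computable G_ST = 1/3."""
    return GenotypeTable(
        ["a1", "a2", "b1", "b2"],
        ["A", "A", "B", "B"],
        ["L1"],
        np.array([[[1, 2]], [[1, 2]], [[1, 1]], [[1, 1]]]),
    )
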