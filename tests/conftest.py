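import numpy as np
import pytest

from fusedrp.entities import EntityIndex
from fusedrp.synthetic import SyntheticConfig, generate


@pytest.fixture
def drug_index():
    return EntityIndex(("d1", "d2", "d3"), "drug")


@pytest.fixture
def cell_index():
    return EntityIndex(("c1", "c2"), "cell")


@pytest.fixture(scope="session")
def tiny_bundle():
    """Small synthetic bundle reused by pipeline-level tests."""
    return generate(SyntheticConfig(n_drugs=12, m_cells=10, n_genes=15,
                                    seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
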