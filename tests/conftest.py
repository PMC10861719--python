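import numpy as np
import pytest

from scdimorph.io import CountMatrix
from scdimorph.synthetic_data import make_default_bundle


@pytest.fixture(scope="session")
def small_bundle():
    """Reduced default bundle shared across test modules (read-only)."""
    return make_default_bundle(seed=11, cells_per_arm=90, n_genes=300)


@pytest.fixture()
def tiny_counts():
    """4 genes x 3 cells with one mito gene; hand-checkable."""
    mat = np.array(
        [
            [0, 5, 2],
            [8, 5, 0],
            [3, 5, 1],
            [1, 5, 0],  # mt- gene
        ]
    )
    return CountMatrix(
        mat,
        np.array(["Ga", "Gb", "Gc", "mt-Gd"], dtype=object),
        np.array(["c1", "c2", "c3"], dtype=object),
    )
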