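import numpy as np
import pytest

from tripath import (
    AssociationMatrix,
    EntityIndex,
    PathParams,
    SimilarityMatrix,
    default_bundle,
)


@pytest.fixture(scope="session")
def chain_tree():
    """Three-disease chain universe: L below P below the root R."""
    return {"L": {"C01.001.001"}, "P": {"C01.001"}, "R": {"C01"}}


@pytest.fixture(scope="session")
def default_params():
    return PathParams()


@pytest.fixture(scope="session")
def bundle():
    """The default masked synthetic bundle (20/10/20, 4 blocks, seed 1)."""
    return default_bundle(seed=1)


@pytest.fixture
def toy_two_layer():
    """2 miRNAs / 2 diseases with one association and one miRNA similarity edge."""
    idx_m = EntityIndex(["a1", "a2"], "mirna")
    idx_d = EntityIndex(["c1", "c2"], "disease")
    S_row = SimilarityMatrix(np.array([[1.0, 0.9], [0.9, 1.0]]), idx_m)
    S_col = SimilarityMatrix(np.eye(2), idx_d)
    A = AssociationMatrix(
        np.array([[1.0, 0.0], [0.0, 0.0]]), idx_m, idx_d, stage="normalized"
    )
    return idx_m, idx_d, S_row, S_col, A


def random_tree_universe(rng, max_diseases=5):
    """Random single-code-per-disease universe over a small fixed code pool."""
    pool = [
        "C01", "C01.001", "C01.002", "C01.001.001", "C01.001.002",
        "C02", "C02.001", "C02.001.001",
    ]
    n = int(rng.integers(2, max_diseases + 1))
    codes = rng.choice(len(pool), size=n, replace=False)
    return {f"dis{k}": {pool[c]} for k, c in enumerate(codes)}
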