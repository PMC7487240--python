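import numpy as np
import pytest

from moltpath import synthetic_data as sd
from moltpath import treekit as tk


@pytest.fixture(scope="session")
def cherry():
    return tk.read_newick("(A:1,B:1);")


@pytest.fixture(scope="session")
def three_tip():
    return tk.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def yule48():
    return sd.simulate_yule_tree(48, seed=42)


@pytest.fixture(scope="session")
def yule100():
    return sd.simulate_yule_tree(100, seed=23)


@pytest.fixture(scope="session")
def warbler_ds():
    return sd.generate_warbler_like_dataset(sd.SimulationConfig(seed=7))


def star_tree(n: int, depth: float = 1.0) -> tk.Phylogeny:
    """Explicit star phylogeny: n tips hanging directly off the root."""
    parent = np.full(n + 1, n, dtype=int)
    parent[n] = -1
    blen = np.full(n + 1, depth)
    blen[n] = 0.0
    children = [[] for _ in range(n + 1)]
    children[n] = list(range(n))
    labels = [f"t{i}" for i in range(n)]
    return tk.Phylogeny(parent, blen, children, labels, labels + ["root"])
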