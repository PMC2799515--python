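import numpy as np
import pytest

from dyhm import Snapshot, snapshot_from_edges


@pytest.fixture
def two_cliques():
    """Two disjoint 5-cliques with known membership (a* vs b*)."""
    edges = [(f"a{i}", f"a{j}") for i in range(5) for j in range(i + 1, 5)]
    edges += [(f"b{i}", f"b{j}") for i in range(5) for j in range(i + 1, 5)]
    snap = snapshot_from_edges(edges)
    labels = np.array(
        [0 if str(v).startswith("a") else 1 for v in snap.vertex_ids]
    )
    return snap, labels


@pytest.fixture
def planted_snapshot():
    """5 groups x 6 vertices, Pwithin=0.9 / Pbetween=0.05, fixed seed."""
    rng = np.random.default_rng(42)
    labels = np.repeat(np.arange(5), 6)
    p = np.where(labels[:, None] == labels[None, :], 0.9, 0.05)
    upper = np.triu(rng.random((30, 30)) < p, k=1)
    A = (upper | upper.T).astype(int)
    return Snapshot(tuple(range(30)), A), labels


def random_snapshot(n, p, seed):
    rng = np.random.default_rng(seed)
    upper = np.triu(rng.random((n, n)) < p, k=1)
    A = (upper | upper.T).astype(int)
    return Snapshot(tuple(range(n)), A)
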