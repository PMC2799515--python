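"""Network snapshots, coupled snapshot series, and variational memberships.

A *snapshot* is one observed state of the network — a time point or a
tissue — with its own set of active vertices and adjacency.  Vertex
identifiers are global across snapshots (gene ids), which is what lets the
smoothness penalty couple a vertex's membership across snapshots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Snapshot:
    """One network state: vertices, an activity mask, and 0/1 adjacency.

    ``adjacency`` is a dense symmetric 0/1 matrix over *all* vertices of
    the snapshot with zero diagonal; edges may only join active vertices.
    Inactive vertices are carried so that a series of snapshots can share
    one global vertex universe.
    """

    vertex_ids: tuple
    adjacency: np.ndarray
    active: np.ndarray = None

    def __post_init__(self) -> None:
        self.vertex_ids = tuple(self.vertex_ids)
        n = len(self.vertex_ids)
        A = np.asarray(self.adjacency)
        if A.shape != (n, n):
            raise ValueError(f"adjacency shape {A.shape} != ({n}, {n})")
        A = (A != 0).astype(np.int8)
        if np.any(A != A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("self-loops are not allowed")
        if self.active is None:
            self.active = np.ones(n, dtype=bool)
        self.active = np.asarray(self.active, dtype=bool)
        if self.active.shape != (n,):
            raise ValueError("activity mask length mismatch")
        if np.any(A[~self.active, :]) or np.any(A[:, ~self.active]):
            raise ValueError("edges incident to inactive vertices")
        self.adjacency = A
        self._index = {v: i for i, v in enumerate(self.vertex_ids)}

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_ids)

    @property
    def n_active(self) -> int:
        return int(self.active.sum())

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def index_of(self, vertex) -> int:
        try:
            return self._index[vertex]
        except KeyError:
            raise KeyError(f"unknown vertex {vertex!r}") from None

    @property
    def active_vertex_ids(self) -> tuple:
        return tuple(v for v, a in zip(self.vertex_ids, self.active) if a)

    def active_subgraph(self) -> tuple[tuple, np.ndarray]:
        """``(active vertex ids, adjacency restricted to active vertices)``."""
        idx = np.flatnonzero(self.active)
        return self.active_vertex_ids, self.adjacency[np.ix_(idx, idx)]

    def degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)


@dataclass
class SnapshotSeries:
    """Ordered snapshots plus the undirected coupling graph between them.

    ``couplings`` lists the snapshot index pairs tied by the smoothness
    penalty — consecutive time points for a simple series, or adjacent
    cells of a tissue-by-stage grid.
    """

    snapshots: list[Snapshot]
    couplings: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        T = len(self.snapshots)
        seen = set()
        norm = []
        for t, s in self.couplings:
            t, s = int(t), int(s)
            if t == s:
                raise ValueError(f"snapshot {t} coupled to itself")
            if not (0 <= t < T and 0 <= s < T):
                raise ValueError(f"coupling ({t}, {s}) out of range 0..{T - 1}")
            key = (min(t, s), max(t, s))
            if key not in seen:
                seen.add(key)
                norm.append(key)
        self.couplings = norm

    def __len__(self) -> int:
        return len(self.snapshots)

    def __getitem__(self, t: int) -> Snapshot:
        return self.snapshots[t]

    def neighbors(self, t: int) -> list[int]:
        """Snapshot indices coupled to snapshot ``t``."""
        out = []
        for a, b in self.couplings:
            if a == t:
                out.append(b)
            elif b == t:
                out.append(a)
        return sorted(out)


@dataclass
class Membership:
    """Per-snapshot variational leaf-assignment probabilities.

    One simplex row of length ``G`` (number of leaves) per *active*
    vertex; ``vertex_ids`` names the rows.
    """

    vertex_ids: tuple
    tau: np.ndarray

    def __post_init__(self) -> None:
        self.vertex_ids = tuple(self.vertex_ids)
        self.tau = np.asarray(self.tau, dtype=float)
        if self.tau.ndim != 2 or self.tau.shape[0] != len(self.vertex_ids):
            raise ValueError("tau must be (n_vertices, n_leaves)")
        if np.any(self.tau < -1e-12) or np.any(self.tau > 1 + 1e-12):
            raise ValueError("tau entries must lie in [0, 1]")
        if not np.allclose(self.tau.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("tau rows must sum to 1 within 1e-9")
        self._index = {v: i for i, v in enumerate(self.vertex_ids)}

    @property
    def n_leaves(self) -> int:
        return self.tau.shape[1]

    def row(self, vertex) -> np.ndarray:
        return self.tau[self._index[vertex]]

    def hard_labels(self) -> np.ndarray:
        """1-based leaf label of each vertex (argmax of its row)."""
        return self.tau.argmax(axis=1) + 1

    def copy(self) -> "Membership":
        return Membership(self.vertex_ids, self.tau.copy())


def snapshot_from_edges(
    edges,
    vertex_ids=None,
    active=None,
) -> Snapshot:
    """Build a snapshot from an iterable of vertex-id pairs.

    Vertices default to the sorted union of endpoint ids; duplicate edges
    collapse and orientation is ignored.
    """
    edges = [(u, v) for u, v in edges]
    if vertex_ids is None:
        vertex_ids = sorted({u for e in edges for u in e}, key=str)
    vertex_ids = tuple(vertex_ids)
    index = {v: i for i, v in enumerate(vertex_ids)}
    A = np.zeros((len(vertex_ids), len(vertex_ids)), dtype=np.int8)
    for u, v in edges:
        i, j = index[u], index[v]
        if i != j:
            A[i, j] = A[j, i] = 1
    return Snapshot(vertex_ids, A, active)
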