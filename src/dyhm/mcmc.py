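"""Collapsed Metropolis-Hastings sampling over hard leaf assignments.

With the Beta edge probabilities integrated out, a hard assignment of
vertices to leaves has the closed-form marginal likelihood of
:func:`dyhm.model.collapsed_log_likelihood`.  Sampling that distribution
with single-vertex reassignment proposals gives the asymptotically correct
posterior over assignments — the oracle against which the variational
approximation's co-membership scores are judged.

A "sweep" here is a single proposal: pick a vertex uniformly, pick one of
the ``G - 1`` other leaves uniformly, accept with
``min(1, exp(delta log-likelihood))``.  The move-specific delta touches
only the moved vertex's leaf, the target leaf, and the internal nodes on
both root paths, so each proposal is cheap and counts are maintained
incrementally (optionally re-verified from scratch in debug mode).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betaln

from .model import SufficientStats, collapsed_log_likelihood
from .network import Snapshot
from .tree import HierTree


def hard_counts(
    A: np.ndarray, z: np.ndarray, tree: HierTree
) -> SufficientStats:
    """Exact per-node edge/non-edge counts of a hard assignment.

    ``z`` holds 0-based leaf indices per vertex.  Every unordered pair
    contributes to the node governing its leaf pair (LCA off-leaf,
    the leaf itself within-leaf).
    """
    n = A.shape[0]
    lca = tree.lca_matrix
    e = np.zeros(tree.n_nodes)
    cnt = np.zeros(tree.n_nodes)
    for i in range(n):
        for j in range(i + 1, n):
            r = lca[z[i], z[j]]
            cnt[r] += 1
            e[r] += A[i, j]
    return SufficientStats(e, cnt - e)


class _Chain:
    """Incremental collapsed sampler state on a raw adjacency."""

    def __init__(
        self,
        A: np.ndarray,
        tree: HierTree,
        z: np.ndarray,
        prior: tuple[float, float],
    ):
        self.A = A
        self.tree = tree
        self.prior = prior
        self.z = np.asarray(z, dtype=np.intp).copy()
        self.G = tree.n_leaves
        self.lca = tree.lca_matrix
        self.neighbors = [np.flatnonzero(A[i]) for i in range(A.shape[0])]
        stats = hard_counts(A, self.z, tree)
        self.e = stats.e
        self.cnt = stats.e + stats.n
        # leaf occupancy
        self.occ = np.bincount(self.z, minlength=self.G).astype(np.int64)

    def _pair_deltas(self, i: int, u: int):
        """Per-node (edge, pair) contribution of vertex i sitting in leaf u.

        Vertex i in leaf u pairs each other vertex j (leaf w) at node
        ``lca[u, w]``; aggregate per leaf w then scatter to nodes.
        """
        d = np.zeros(self.G)  # edges from i into each leaf
        for j in self.neighbors[i]:
            d[self.z[j]] += 1.0
        c = self.occ.astype(float).copy()
        c[self.z[i]] -= 1.0  # exclude i itself
        nodes = self.lca[u]
        de = np.zeros(self.tree.n_nodes)
        dc = np.zeros(self.tree.n_nodes)
        np.add.at(de, nodes, d)
        np.add.at(dc, nodes, c)
        return de, dc

    def delta_loglik(self, i: int, v: int) -> tuple[float, np.ndarray, np.ndarray]:
        """Log-likelihood change of moving vertex ``i`` to leaf ``v``."""
        a0, b0 = self.prior
        u = self.z[i]
        de_u, dc_u = self._pair_deltas(i, u)
        # counts with i detached
        e1 = self.e - de_u
        c1 = self.cnt - dc_u
        de_v, dc_v = self._pair_deltas(i, v)
        e2 = e1 + de_v
        c2 = c1 + dc_v
        touched = np.flatnonzero((dc_u != 0) | (dc_v != 0))
        old = betaln(self.e[touched] + a0, self.cnt[touched] - self.e[touched] + b0)
        new = betaln(e2[touched] + a0, c2[touched] - e2[touched] + b0)
        return float(np.sum(new - old)), e2, c2

    def apply(self, i: int, v: int, e2: np.ndarray, c2: np.ndarray) -> None:
        self.occ[self.z[i]] -= 1
        self.occ[v] += 1
        self.z[i] = v
        self.e = e2
        self.cnt = c2

    def loglik(self) -> float:
        stats = SufficientStats(self.e, self.cnt - self.e)
        return collapsed_log_likelihood(stats, self.prior)

    def check(self) -> None:
        """Debug: incremental counts must equal recomputation from scratch."""
        stats = hard_counts(self.A, self.z, self.tree)
        if not (
            np.allclose(stats.e, self.e)
            and np.allclose(stats.e + stats.n, self.cnt)
        ):
            raise AssertionError("incremental counts drifted from truth")


def mh_step(
    assignment: np.ndarray,
    snapshot: Snapshot,
    tree: HierTree,
    prior: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """One Metropolis-Hastings proposal; returns the (new) hard assignment.

    Proposes moving one uniformly chosen vertex to a uniformly chosen leaf
    (possibly its current one, which keeps the chain aperiodic even when
    every move is accepted) and accepts with ``min(1, exp(delta))`` where
    delta is the collapsed log-likelihood change.
    """
    _, A = snapshot.active_subgraph()
    chain = _Chain(A, tree, assignment, prior)
    i = int(rng.integers(A.shape[0]))
    v = int(rng.integers(tree.n_leaves))
    if v != chain.z[i]:
        delta, e2, c2 = chain.delta_loglik(i, v)
        if np.log(rng.random()) < delta:
            chain.apply(i, v, e2, c2)
    return chain.z.copy()


@dataclass
class McmcRun:
    """Result of a co-membership sampling run."""

    co_membership: np.ndarray
    vertex_ids: tuple
    n_samples: int
    sweeps: int
    burn_in: int
    thin: int
    seed: int | None
    final_loglik: float


def sample_co_membership(
    snapshot: Snapshot,
    depth: int,
    sweeps: int = 100_000,
    burn_in: int | None = None,
    thin: int = 10,
    seed: int | None = None,
    prior: tuple[float, float] = (1.0, 1.0),
    debug_check_every: int | None = None,
) -> McmcRun:
    """Posterior co-membership scores from the collapsed sampler.

    Runs ``sweeps`` single-vertex proposals from a random assignment,
    discards ``burn_in`` (default 20% of sweeps), retains every ``thin``-th
    state, and averages the same-leaf indicator over retained samples.
    The returned matrix is symmetric with unit diagonal.
    """
    if burn_in is None:
        burn_in = sweeps // 5
    if sweeps <= burn_in:
        raise ValueError("sweeps must exceed burn_in")
    ids, A = snapshot.active_subgraph()
    n = A.shape[0]
    tree = HierTree(depth, prior)
    rng = np.random.default_rng(seed)
    z0 = rng.integers(tree.n_leaves, size=n)
    chain = _Chain(A, tree, z0, prior)
    G = tree.n_leaves
    co = np.zeros((n, n))
    n_samples = 0
    # pre-draw proposal randomness in blocks for speed
    block = 8192
    step = 0
    while step < sweeps:
        k = min(block, sweeps - step)
        vi = rng.integers(n, size=k)
        vl = rng.integers(G, size=k)
        logu = np.log(rng.random(size=k))
        for t in range(k):
            i = int(vi[t])
            v = int(vl[t])
            if v != chain.z[i]:
                delta, e2, c2 = chain.delta_loglik(i, v)
                if logu[t] < delta:
                    chain.apply(i, v, e2, c2)
            step += 1
            if debug_check_every and step % debug_check_every == 0:
                chain.check()
            if step > burn_in and step % thin == 0:
                same = chain.z[:, None] == chain.z[None, :]
                co += same
                n_samples += 1
    if n_samples == 0:
        raise ValueError("no samples retained; lower thin or raise sweeps")
    co /= n_samples
    np.fill_diagonal(co, 1.0)
    return McmcRun(
        co_membership=co,
        vertex_ids=ids,
        n_samples=n_samples,
        sweeps=sweeps,
        burn_in=burn_in,
        thin=thin,
        seed=seed,
        final_loglik=chain.loglik(),
    )
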