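"""Variational mean-field inference for a single static snapshot.

Coordinate ascent on the evidence lower bound alternates two exact
conditional updates until the bound stops improving:

* tree parameters — with memberships fixed, every node's Beta posterior is
  conjugate: ``a_r = a0 + e_r``, ``b_r = b0 + n_r``, with the expectations
  ``E[log theta_r] = psi(a_r) - psi(a_r + b_r)`` entering the assignment
  field through the digamma function;
* memberships — with tree parameters fixed, each vertex's row is a softmax
  over its per-leaf field, one asynchronous pass in randomized order.

Each step maximizes the bound exactly given the rest of the state, so the
objective is non-decreasing sweep over sweep.  The landscape is multimodal;
the fit is repeated from random restarts and the best bound kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betaln, digamma

from .model import SufficientStats, expected_counts
from .network import Membership, Snapshot
from .tree import HierTree

TAU_FLOOR = 1e-12  # membership entries are floored before logs


@dataclass
class VBState:
    """Converged (or best-so-far) state of one variational fit."""

    membership: Membership
    tree: HierTree
    elbo_trace: np.ndarray
    seed: int | None = None
    restart_index: int = 0
    converged: bool = True
    n_sweeps: int = 0

    @property
    def elbo(self) -> float:
        return float(self.elbo_trace[-1])


def update_tree_params(
    stats: SufficientStats,
    prior: tuple[float, float],
    tree: HierTree,
) -> HierTree:
    """Conjugate Beta update ``a = a0 + e``, ``b = b0 + n`` for every node."""
    a0, b0 = prior
    if stats.n_nodes != tree.n_nodes:
        raise ValueError("statistics do not match the tree")
    return HierTree(tree.depth, (a0, b0), a0 + stats.e, b0 + stats.n)


def update_assignment(field: np.ndarray) -> np.ndarray:
    """Softmax of the per-leaf field, stabilized by max subtraction."""
    field = np.asarray(field, dtype=float)
    if np.all(np.isneginf(field)):
        raise ValueError("assignment field is -inf for every leaf")
    x = np.exp(field - field.max())
    return x / x.sum()


def _split_weights(tree: HierTree) -> tuple[np.ndarray, np.ndarray]:
    """``(W_edge, W_gap)``: G x G matrices of node log-expectations by pair.

    Entry ``(u, w)`` is ``E[log theta]`` (resp. ``E[log(1-theta)]``) of the
    node governing a vertex pair placed in leaves ``u`` and ``w`` — the LCA
    for ``u != w``, the leaf itself on the diagonal.  The assignment field
    of vertex ``i`` is then ``W_edge @ d_i + W_gap @ m_i`` where ``d_i`` is
    its expected edge count into each leaf and ``m_i`` the expected leaf
    occupancy excluding ``i``.
    """
    lca = tree.lca_matrix
    return tree.elog_theta[lca], tree.elog_1m_theta[lca]


def _field_row(
    A: np.ndarray,
    T: np.ndarray,
    i: int,
    W_edge: np.ndarray,
    W_gap: np.ndarray,
    colsum: np.ndarray,
) -> np.ndarray:
    d = A[i] @ T
    m = colsum - T[i]
    return W_edge @ d + W_gap @ (m - d)


def assignment_field(
    vertex,
    snapshot: Snapshot,
    tau: Membership,
    tree: HierTree,
) -> np.ndarray:
    """Per-leaf log-field of one vertex given everyone else's membership.

    For leaf ``u`` the field accumulates, over ``u``'s ancestors ``r`` (with
    opposite-side leaf set ``S``) and ``u`` itself, the expected-edge and
    expected-non-edge weights ``d E[log theta] + (m - d) E[log(1-theta)]``.
    Adding a constant to all node expectations shifts every leaf equally
    and leaves the softmax unchanged.
    """
    ids, A = snapshot.active_subgraph()
    if tuple(tau.vertex_ids) != tuple(ids):
        raise ValueError("membership rows do not match the active vertex set")
    try:
        i = ids.index(vertex)
    except ValueError:
        raise ValueError(f"vertex {vertex!r} is not active") from None
    W_edge, W_gap = _split_weights(tree)
    T = tau.tau
    return _field_row(A, T, i, W_edge, W_gap, T.sum(axis=0))


def _beta_entropy(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return (
        betaln(a, b)
        - (a - 1) * digamma(a)
        - (b - 1) * digamma(b)
        + (a + b - 2) * digamma(a + b)
    )


def elbo(
    snapshot: Snapshot,
    tau: Membership,
    tree: HierTree,
    prior: tuple[float, float] = (1.0, 1.0),
) -> float:
    """Evidence lower bound of the factorized surrogate.

    Expected log-joint (Bernoulli terms with digamma expectations, Beta
    prior, uniform leaf prior on assignments) plus the surrogate entropy
    (categorical rows and Beta factors).  Equals the negative KL divergence
    to the true posterior up to the model's log-evidence constant; after a
    conjugate tree update it collapses to the Beta-function form
    ``sum_r [log B(a_r, b_r) - log B(a0, b0)]`` plus the assignment
    entropy minus ``N log G``.
    """
    stats = expected_counts(snapshot, tau, tree)
    a0, b0 = prior
    elt, el1 = tree.elog_theta, tree.elog_1m_theta
    like = np.sum((stats.e + a0 - 1) * elt + (stats.n + b0 - 1) * el1)
    like -= tree.n_nodes * betaln(a0, b0)
    ent_beta = np.sum(_beta_entropy(tree.a, tree.b))
    T = np.clip(tau.tau, TAU_FLOOR, None)
    ent_tau = -np.sum(tau.tau * np.log(T))
    n = tau.tau.shape[0]
    return float(like + ent_beta + ent_tau - n * np.log(tree.n_leaves))


def _spectral_labels(
    S: np.ndarray, depth: int, rng: np.random.Generator
) -> np.ndarray:
    """Hierarchical spectral bisection of a (weighted) adjacency matrix.

    Recursively splits the vertex set along the Fiedler vector, ``depth``
    levels deep, assigning each part the leaf index given by its
    left/right path — a structure-aware initial partition that mirrors the
    model's binary hierarchy.  Degenerate blocks fall back to random
    sides, so the labels remain usable on edgeless inputs.
    """
    n = S.shape[0]
    labels = np.zeros(n, dtype=np.int64)

    def rec(idx: np.ndarray, d: int, base: int) -> None:
        if d == 0 or idx.size < 2:
            labels[idx] = base
            return
        side = _bisect(S[np.ix_(idx, idx)], rng)
        rec(idx[~side], d - 1, base)
        rec(idx[side], d - 1, base + 2 ** (d - 1))

    rec(np.arange(n), depth, 0)
    return labels


def _hard_tau(z: np.ndarray, G: int) -> np.ndarray:
    """One-hot membership rows (floored) from hard labels.

    Hard initializations matter here: near-uniform rows are an exactly
    stable fixed point of the mean-field iteration (a flat membership
    makes every node's expected density equal, which makes the assignment
    field constant across leaves), so soft random starts collapse.
    """
    T = np.full((z.shape[0], G), TAU_FLOOR)
    T[np.arange(z.shape[0]), z] = 1.0
    return T / T.sum(axis=1, keepdims=True)


def _ascend(
    A: np.ndarray,
    T: np.ndarray,
    tree: HierTree,
    prior: tuple[float, float],
    rng: np.random.Generator,
    tol: float,
    max_sweeps: int,
    trace: list[float],
) -> tuple[HierTree, bool]:
    """Coordinate-ascent sweeps until the bound stalls; mutates T, trace."""
    n = A.shape[0]
    ids = tuple(range(n))
    snapshot = Snapshot(ids, A)
    converged = False
    for _ in range(max_sweeps):
        stats = expected_counts(snapshot, Membership(ids, T), tree)
        tree = update_tree_params(stats, prior, tree)
        W_edge, W_gap = _split_weights(tree)
        colsum = T.sum(axis=0)
        for i in rng.permutation(n):
            f = _field_row(A, T, i, W_edge, W_gap, colsum)
            new = update_assignment(f)
            colsum += new - T[i]
            T[i] = new
        trace.append(elbo(snapshot, Membership(ids, T), tree, prior))
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol * (
            1 + abs(trace[-1])
        ):
            converged = True
            break
    return tree, converged


def _bisect(subA: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Two-part split of a small vertex block by the Fiedler vector sign."""
    m = subA.shape[0]
    lap = np.diag(subA.sum(axis=1)) - subA
    _, vec = np.linalg.eigh(lap)
    side = vec[:, 1] >= 0 if m > 1 else np.zeros(m, bool)
    if side.all() or not side.any():
        side = rng.random(m) < 0.5
        if side.all() or not side.any():
            side[0] = ~side[0]
    return side


def _split_refine(
    A: np.ndarray,
    T: np.ndarray,
    tree: HierTree,
    prior: tuple[float, float],
    rng: np.random.Generator,
    tol: float,
    max_sweeps: int,
    trace: list[float],
) -> HierTree:
    """Escape merged-block optima by trying ELBO-improving leaf splits.

    Coordinate ascent cannot separate two planted groups that collapsed
    into one leaf (no single-vertex move improves the bound), so after
    convergence each multiply-occupied leaf is tentatively bisected along
    the Fiedler vector of its induced subgraph into an unoccupied leaf and
    re-ascended; the split is kept only when the bound improves, so the
    recorded trace stays monotone.
    """
    n = A.shape[0]
    G = tree.n_leaves
    improved = True
    rounds = 0
    while improved and rounds < G:
        improved = False
        rounds += 1
        z = T.argmax(axis=1)
        occ = np.bincount(z, minlength=G)
        empty = np.flatnonzero(occ == 0)
        if empty.size == 0:
            break
        for u in np.argsort(-occ):
            if occ[u] < 2:
                break
            members = np.flatnonzero(z == u)
            side = _bisect(A[np.ix_(members, members)].astype(float), rng)
            T_try = T.copy()
            moved = members[side]
            T_try[moved] = TAU_FLOOR
            T_try[moved, empty[0]] = 1.0
            T_try /= T_try.sum(axis=1, keepdims=True)
            sub_trace: list[float] = []
            tree_try, _ = _ascend(
                A, T_try, tree.copy(), prior, rng, tol, max_sweeps, sub_trace
            )
            if sub_trace[-1] > trace[-1] + tol * (1 + abs(trace[-1])):
                T[:] = T_try
                tree = tree_try
                trace.append(sub_trace[-1])
                improved = True
                break
    return tree


def _run_restart(
    A: np.ndarray,
    depth: int,
    prior: tuple[float, float],
    rng: np.random.Generator,
    tol: float,
    max_sweeps: int,
    restart_index: int = 0,
) -> tuple[np.ndarray, HierTree, list[float], bool, int]:
    """One coordinate-ascent run on a raw adjacency; returns raw state.

    Restart 0 starts from the pure spectral-bisection partition of the
    adjacency; later restarts perturb it (15% of vertices moved to random
    leaves) for diversity.
    """
    n = A.shape[0]
    tree = HierTree(depth, prior)
    G = tree.n_leaves
    z = _spectral_labels(A.astype(float), depth, rng)
    if restart_index > 0:
        mask = rng.random(n) < 0.15
        z = z.copy()
        z[mask] = rng.integers(G, size=int(mask.sum()))
    T = _hard_tau(z, G)
    trace: list[float] = []
    tree, converged = _ascend(A, T, tree, prior, rng, tol, max_sweeps, trace)
    if converged:
        tree = _split_refine(A, T, tree, prior, rng, tol, max_sweeps, trace)
    return T, tree, trace, converged, len(trace)


def fit_static(
    snapshot: Snapshot,
    depth: int,
    restarts: int = 7,
    seed: int | np.random.SeedSequence | None = None,
    tol: float = 1e-6,
    max_sweeps: int = 500,
    prior: tuple[float, float] = (1.0, 1.0),
) -> VBState:
    """Fit the hierarchical model to one snapshot; best bound over restarts.

    Restarts start from hard spectral-bisection partitions (perturbed
    after the first) and run coordinate ascent until the relative bound
    change drops below ``tol`` or ``max_sweeps`` is hit (``converged``
    flags the latter), followed by leaf-split refinement.
    """
    ids, A = snapshot.active_subgraph()
    if len(ids) == 0:
        raise ValueError("snapshot has no active vertices")
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    best: VBState | None = None
    for r, child in enumerate(ss.spawn(restarts)):
        rng = np.random.default_rng(child)
        T, tree, trace, conv, sweeps = _run_restart(
            A, depth, prior, rng, tol, max_sweeps, restart_index=r
        )
        state = VBState(
            membership=Membership(ids, T),
            tree=tree,
            elbo_trace=np.asarray(trace),
            seed=seed if isinstance(seed, int) else None,
            restart_index=r,
            converged=conv,
            n_sweeps=sweeps,
        )
        if best is None or state.elbo > best.elbo:
            best = state
    return best
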