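"""Sufficient statistics and the collapsed likelihood of the hierarchical model.

Under the hierarchical stochastic block model every unordered pair of
active vertices contributes one Bernoulli observation to exactly one tree
node: the lowest common ancestor of the two leaves the vertices occupy
(an internal node when they sit in different leaves, the leaf itself when
they share one).  The per-node expected edge counts ``e_r`` and non-edge
counts ``n_r`` under a mean-field membership are therefore the model's
sufficient statistics, and with Beta priors the edge probabilities
integrate out in closed form (Beta-binomial conjugacy).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betaln

from .network import Membership, Snapshot
from .tree import HierTree

#: log2-ratio clip for enrichment reports; keeps zero-edge nodes finite.
ENRICHMENT_CLIP = 10.0


@dataclass
class SufficientStats:
    """Expected edge / non-edge counts per tree node, in heap order.

    ``e[r]`` and ``n[r]`` are the expected numbers of edges and non-edges
    whose pair splits at node ``r`` (internal nodes: left x right
    descendant pairs; leaves: within-leaf pairs).
    """

    e: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        self.e = np.asarray(self.e, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if self.e.shape != self.n.shape or self.e.ndim != 1:
            raise ValueError("e and n must be equal-length vectors")
        if np.any(self.e < -1e-9) or np.any(self.n < -1e-9):
            raise ValueError("counts must be non-negative")
        np.clip(self.e, 0.0, None, out=self.e)
        np.clip(self.n, 0.0, None, out=self.n)

    @property
    def n_nodes(self) -> int:
        return self.e.shape[0]

    def total_pairs(self) -> float:
        return float(self.e.sum() + self.n.sum())


def expected_counts(
    snapshot: Snapshot, tau: Membership, tree: HierTree
) -> SufficientStats:
    """Mean-field expected edge / non-edge counts for every tree node.

    For an internal node ``r`` with descendant leaf sets ``L`` and ``R``,

        e_r = sum_{i<j} A_ij (tau_i[L] tau_j[R] + tau_i[R] tau_j[L])

    with ``tau_i[S] = sum_{u in S} tau_iu``, and ``n_r`` the same with
    ``1 - A_ij``; leaf counts use ``tau_iu tau_ju``.  Pair independence is
    the mean-field assumption: each pair's split probability is the product
    of the two membership rows.
    """
    ids, A = snapshot.active_subgraph()
    if tuple(tau.vertex_ids) != tuple(ids):
        raise ValueError("membership rows do not match the active vertex set")
    if tau.n_leaves != tree.n_leaves:
        raise ValueError("membership width does not match the tree")
    T = tau.tau
    G = tree.n_leaves
    e = np.zeros(tree.n_nodes)
    n = np.zeros(tree.n_nodes)
    AT = A @ T  # (i, u) -> expected edges from i into leaf u
    col = T.sum(axis=0)
    # leaves: e_u = 1/2 tau_u' A tau_u ; pair count from occupancy moments
    e_leaf = 0.5 * np.einsum("iu,iu->u", T, AT)
    t_leaf = 0.5 * (col**2 - np.einsum("iu,iu->u", T, T))
    e[G - 1 :] = e_leaf
    n[G - 1 :] = t_leaf - e_leaf
    for r in tree.internal_nodes:
        left, right = tree.children(r)
        llo, lhi = tree.leaf_range(left)
        rlo, rhi = tree.leaf_range(right)
        li = T[:, llo:lhi].sum(axis=1)
        ri = T[:, rlo:rhi].sum(axis=1)
        e_r = li @ AT[:, rlo:rhi].sum(axis=1)
        t_r = li.sum() * ri.sum() - li @ ri
        e[r] = e_r
        n[r] = t_r - e_r
    return SufficientStats(e, n)


def collapsed_log_likelihood(
    stats: SufficientStats, prior: tuple[float, float] = (1.0, 1.0)
) -> float:
    """Log marginal likelihood with every node's theta integrated out.

    ``sum_r [ log B(e_r + a0, n_r + b0) - log B(a0, b0) ]`` — exact for
    hard (0/1) counts, and the corresponding Jensen bound term for
    fractional mean-field counts.
    """
    a0, b0 = prior
    if a0 <= 0 or b0 <= 0:
        raise ValueError("prior parameters must be positive")
    return float(
        np.sum(betaln(stats.e + a0, stats.n + b0) - betaln(a0, b0))
    )


def node_enrichment(stats: SufficientStats, snapshot: Snapshot) -> np.ndarray:
    """Per-node log2 edge-density enrichment relative to the global density.

    ``log2( [e_r / (e_r + n_r)] / rho )`` with ``rho`` the snapshot's
    overall edge density over active pairs; clipped to ±``ENRICHMENT_CLIP``
    so zero-edge nodes report as strong depletion rather than −inf.  Nodes
    with no expected pairs are flagged NaN.
    """
    m = snapshot.n_edges
    if m == 0:
        raise ValueError("enrichment is undefined for an empty graph")
    n_act = snapshot.n_active
    rho = m / (n_act * (n_act - 1) / 2)
    tot = stats.e + stats.n
    out = np.full(stats.n_nodes, np.nan)
    occ = tot > 1e-12
    with np.errstate(divide="ignore"):
        out[occ] = np.log2(stats.e[occ] / tot[occ] / rho)
    out[occ] = np.clip(out[occ], -ENRICHMENT_CLIP, ENRICHMENT_CLIP)
    return out
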