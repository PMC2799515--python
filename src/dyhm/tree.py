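"""Fixed-depth perfect binary trees with Beta edge-probability parameters.

The hierarchical block model assigns network vertices to the leaves of a
perfect binary tree of depth ``D`` (``G = 2**D`` leaves).  Every node carries
a Bernoulli edge probability ``theta_r`` with a Beta posterior ``(a_r, b_r)``:
internal nodes govern edges between their left and right descendant leaf
sets, leaves govern within-leaf edges.

Nodes are stored in heap order: node 0 is the root, node ``r`` has children
``2r + 1`` and ``2r + 2``; internal nodes occupy indices ``0 .. G-2`` and
leaves ``G-1 .. 2G-2``.  Leaf *labels* used in reports are 1-based
left-to-right (leaf 1 is the leftmost terminal, leaf G the rightmost).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma


@dataclass
class HierTree:
    """Perfect binary tree of a fixed depth with per-node Beta parameters.

    Parameters
    ----------
    depth
        Number of branchings; the tree has ``G = 2**depth`` leaves and
        ``G - 1`` internal nodes.
    prior
        ``(a0, b0)`` Beta prior shared by every node; the default ``(1, 1)``
        is the flat, non-informative prior.
    a, b
        Per-node Beta posterior parameters in heap order (length
        ``2G - 1``).  Initialized to the prior when omitted.
    """

    depth: int
    prior: tuple[float, float] = (1.0, 1.0)
    a: np.ndarray = field(default=None, repr=False)
    b: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError(f"tree depth must be >= 1, got {self.depth}")
        a0, b0 = self.prior
        if a0 <= 0 or b0 <= 0:
            raise ValueError("Beta prior parameters must be positive")
        if self.a is None:
            self.a = np.full(self.n_nodes, float(a0))
        if self.b is None:
            self.b = np.full(self.n_nodes, float(b0))
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != (self.n_nodes,) or self.b.shape != (self.n_nodes,):
            raise ValueError("a/b must have one entry per tree node")
        if np.any(self.a <= 0) or np.any(self.b <= 0):
            raise ValueError("Beta parameters must be positive")
        # leaf_lo[r]:leaf_hi[r] is the contiguous 0-based range of leaves
        # under node r (a perfect tree keeps descendant leaves contiguous).
        lo = np.empty(self.n_nodes, dtype=np.int64)
        hi = np.empty(self.n_nodes, dtype=np.int64)
        G = self.n_leaves
        for r in range(self.n_nodes - 1, -1, -1):
            if r >= G - 1:  # leaf
                lo[r] = r - (G - 1)
                hi[r] = lo[r] + 1
            else:
                lo[r] = lo[2 * r + 1]
                hi[r] = hi[2 * r + 2]
        self._leaf_lo, self._leaf_hi = lo, hi
        self._lca = None

    # -- topology ---------------------------------------------------------

    @property
    def n_leaves(self) -> int:
        return 2**self.depth

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_leaves - 1

    @property
    def internal_nodes(self) -> range:
        return range(self.n_leaves - 1)

    @property
    def leaf_nodes(self) -> range:
        return range(self.n_leaves - 1, self.n_nodes)

    def leaf_node(self, leaf_label: int) -> int:
        """Heap index of the 1-based leaf label."""
        if not 1 <= leaf_label <= self.n_leaves:
            raise ValueError(
                f"leaf label {leaf_label} outside 1..{self.n_leaves}"
            )
        return self.n_leaves - 1 + (leaf_label - 1)

    def leaf_range(self, node: int) -> tuple[int, int]:
        """0-based ``[lo, hi)`` range of leaves under ``node``."""
        return int(self._leaf_lo[node]), int(self._leaf_hi[node])

    def children(self, node: int) -> tuple[int, int]:
        if node >= self.n_leaves - 1:
            raise ValueError(f"node {node} is a leaf")
        return 2 * node + 1, 2 * node + 2

    @property
    def lca_matrix(self) -> np.ndarray:
        """``G x G`` matrix of the heap node governing each leaf pair.

        Off-diagonal entry ``(u, v)`` is the lowest common ancestor of
        leaves ``u`` and ``v`` (the internal node whose Bernoulli parameter
        a pair of vertices split across those leaves contributes to);
        diagonal entry ``(u, u)`` is leaf ``u``'s own heap index (the
        within-leaf parameter).
        """
        if self._lca is None:
            G = self.n_leaves
            lca = np.empty((G, G), dtype=np.int64)
            for u in range(G):
                nu = G - 1 + u
                for v in range(u, G):
                    x, y = nu, G - 1 + v
                    while x != y:
                        if x > y:
                            x = (x - 1) // 2
                        else:
                            y = (y - 1) // 2
                    lca[u, v] = lca[v, u] = x
            self._lca = lca
        return self._lca

    # -- posterior expectations ------------------------------------------

    @property
    def elog_theta(self) -> np.ndarray:
        """Per-node ``E[log theta] = psi(a) - psi(a + b)``."""
        return digamma(self.a) - digamma(self.a + self.b)

    @property
    def elog_1m_theta(self) -> np.ndarray:
        """Per-node ``E[log(1 - theta)] = psi(b) - psi(a + b)``."""
        return digamma(self.b) - digamma(self.a + self.b)

    def copy(self) -> "HierTree":
        return HierTree(self.depth, self.prior, self.a.copy(), self.b.copy())


def leaf_ancestry(tree: HierTree, leaf_label: int) -> list[tuple[int, str]]:
    """Root-to-leaf path of internal nodes for a 1-based leaf label.

    Returns ``[(node, side), ...]`` from the root down, where ``side`` is
    ``"left"`` or ``"right"`` depending on which child subtree contains the
    leaf.  The path of a depth-``D`` tree always has length ``D``.
    """
    node = tree.leaf_node(leaf_label)
    path: list[tuple[int, str]] = []
    while node != 0:
        parent = (node - 1) // 2
        side = "left" if node == 2 * parent + 1 else "right"
        path.append((parent, side))
        node = parent
    path.reverse()
    return path


def tree_to_json(
    tree: HierTree,
    path: str | None = None,
    enrichment: np.ndarray | None = None,
) -> str:
    """Serialize a tree (and optional per-node enrichment) to JSON."""
    G = tree.n_leaves
    nodes = []
    for r in range(tree.n_nodes):
        rec: dict = {
            "id": r,
            "a": float(tree.a[r]),
            "b": float(tree.b[r]),
        }
        if r < G - 1:
            rec["children"] = [2 * r + 1, 2 * r + 2]
        else:
            rec["leaf_label"] = r - (G - 1) + 1
        if enrichment is not None:
            e = enrichment[r]
            rec["enrichment"] = None if np.isnan(e) else float(e)
        nodes.append(rec)
    doc = {
        "depth": tree.depth,
        "prior": list(tree.prior),
        "nodes": nodes,
    }
    text = json.dumps(doc, indent=1)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def tree_from_json(source: str) -> HierTree:
    """Inverse of :func:`tree_to_json`; ``source`` is a path or JSON text."""
    if source.lstrip().startswith("{"):
        doc = json.loads(source)
    else:
        with open(source) as fh:
            doc = json.load(fh)
    depth = int(doc["depth"])
    n_nodes = 2 ** (depth + 1) - 1
    a = np.empty(n_nodes)
    b = np.empty(n_nodes)
    for rec in doc["nodes"]:
        a[rec["id"]] = rec["a"]
        b[rec["id"]] = rec["b"]
    return HierTree(depth, tuple(doc["prior"]), a, b)
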