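"""Shared-neighbor hypergeometric baseline for pairwise co-membership.

Two vertices that belong to the same module tend to share interaction
partners.  The baseline scores every vertex pair by the upper-tail
hypergeometric probability of observing at least their number of shared
neighbors by chance, given both degrees — smaller p-values mean stronger
co-membership evidence.  Both endpoints are excluded from each other's
neighbor set and from the sampling universe.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .network import Snapshot


def shared_neighbor_pvalue(u, v, snapshot: Snapshot) -> float:
    """Upper-tail p-value for the shared neighbors of vertices ``u``, ``v``.

    With ``n`` active vertices other than ``u`` and ``v``,
    ``K = |N(u) \\ {v}|``, ``D = |N(v) \\ {u}|`` and
    ``k = |N(u) ∩ N(v)|``, returns ``P(X >= k)`` for
    ``X ~ Hypergeometric(n, K, D)``; ``k = 0`` gives exactly 1.
    """
    if u == v:
        raise ValueError("u and v must differ")
    i, j = snapshot.index_of(u), snapshot.index_of(v)
    if not (snapshot.active[i] and snapshot.active[j]):
        raise ValueError("both vertices must be active")
    A = snapshot.adjacency
    Nu = set(map(int, A[i].nonzero()[0]))
    Nv = set(map(int, A[j].nonzero()[0]))
    k = len(Nu & Nv)  # cannot contain i or j (no self-loops)
    K = len(Nu - {j})
    D = len(Nv - {i})
    n = snapshot.n_active - 2
    return float(hypergeom.sf(k - 1, n, K, D))


def rank_all_pairs(snapshot: Snapshot) -> pd.DataFrame:
    """All active vertex pairs ranked by shared-neighbor significance.

    Ascending by p-value; ties break by shared-neighbor count (descending)
    then by the lexicographic pair id.  ``score = -log(p)`` is the
    ranking score used in precision-recall evaluation.
    """
    ids, A = snapshot.active_subgraph()
    if len(ids) < 2:
        raise ValueError("need at least 2 active vertices")
    rows = []
    nbrs = [set(map(int, A[i].nonzero()[0])) for i in range(len(ids))]
    n = len(ids) - 2
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            k = len(nbrs[i] & nbrs[j])
            K = len(nbrs[i] - {j})
            D = len(nbrs[j] - {i})
            p = float(hypergeom.sf(k - 1, n, K, D))
            rows.append((str(ids[i]), str(ids[j]), k, p))
    df = pd.DataFrame(rows, columns=["u", "v", "shared", "p"])
    df["score"] = -np.log(df["p"].clip(lower=np.finfo(float).tiny))
    df = df.sort_values(
        ["p", "shared", "u", "v"], ascending=[True, False, True, True]
    ).reset_index(drop=True)
    return df


def pvalue_score_matrix(snapshot: Snapshot) -> np.ndarray:
    """Symmetric ``-log p`` matrix over the active vertices.

    Convenience form of :func:`rank_all_pairs` for pairwise evaluation
    against planted truth; rows/columns follow the active vertex order.
    """
    ids, A = snapshot.active_subgraph()
    n = len(ids)
    nbrs = [set(map(int, A[i].nonzero()[0])) for i in range(n)]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            k = len(nbrs[i] & nbrs[j])
            K = len(nbrs[i] - {j})
            D = len(nbrs[j] - {i})
            p = float(hypergeom.sf(k - 1, n - 2, K, D))
            s = -np.log(max(p, np.finfo(float).tiny))
            out[i, j] = out[j, i] = s
    return out
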