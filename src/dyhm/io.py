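"""Readers, writers, degree pruning, and snapshot-series construction.

File formats are deliberately plain: tab-separated edge lists (two vertex
columns, optional header), a vertices-by-snapshots activity matrix (TSV,
first column the vertex id, header row naming the snapshots), and a YAML
series manifest tying per-snapshot edge files, the activity matrix, and
the coupling pairs together.
"""

from __future__ import annotations

import logging
import os

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .network import Snapshot, SnapshotSeries, snapshot_from_edges

logger = logging.getLogger(__name__)

_HEADER_TOKENS = {
    "source", "target", "from", "to", "node1", "node2",
    "vertex1", "vertex2", "u", "v",
}


def read_edge_list(path: str) -> Snapshot:
    """Read an undirected TSV edge list into a snapshot.

    Lines hold two tab-separated vertex ids (treated as strings); a header
    row of recognizable column names is skipped.  Duplicate and reversed
    edges collapse; self-loops are dropped with a logged warning.
    Malformed lines raise with their line number.
    """
    edges: list[tuple[str, str]] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise ValueError(
                    f"{path}:{lineno}: expected two tab-separated vertex ids,"
                    f" got {line!r}"
                )
            u, v = parts[0].strip(), parts[1].strip()
            if lineno == 1 and u.lower() in _HEADER_TOKENS and v.lower() in _HEADER_TOKENS:
                continue
            if u == v:
                dropped += 1
                logger.warning("%s:%d: dropping self-loop %s-%s", path, lineno, u, v)
                continue
            edges.append((u, v))
    return snapshot_from_edges(edges)


def write_edge_list(snapshot: Snapshot, path: str) -> None:
    """Write the active edges of a snapshot as a headerless TSV."""
    ids = snapshot.vertex_ids
    A = snapshot.adjacency
    with open(path, "w") as fh:
        for i, j in zip(*np.triu_indices_from(A, k=1)):
            if A[i, j]:
                fh.write(f"{ids[i]}\t{ids[j]}\n")


def prune_low_degree(snapshot: Snapshot, k: int = 3) -> Snapshot:
    """Iteratively remove vertices of degree <= k until none remain.

    Equivalent to keeping the (k+1)-core: the result is the unique maximal
    subgraph in which every vertex has degree > k, independent of removal
    order, and applying the operation twice equals applying it once.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    ids, A = snapshot.active_subgraph()
    g = nx.Graph()
    g.add_nodes_from(ids)
    iu, ju = np.nonzero(np.triu(A, k=1))
    g.add_edges_from((ids[i], ids[j]) for i, j in zip(iu, ju))
    core = nx.k_core(g, k + 1)
    keep = [v for v in ids if v in core]
    return snapshot_from_edges(core.edges(), vertex_ids=keep)


def read_activity_matrix(path: str) -> pd.DataFrame:
    """Vertices-by-snapshots activity table (TSV, vertex ids as index)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_activity_matrix(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t")


def build_series(
    base: Snapshot,
    activity: pd.DataFrame,
    threshold: float = 1.0,
    couplings: list[tuple[int, int]] | None = None,
) -> SnapshotSeries:
    """Extract active subnetworks of a base network per activity column.

    A vertex is active in a snapshot when its activity value is >= the
    threshold (presence call on a binary matrix at the default threshold
    of 1); each snapshot keeps the base vertex universe with the induced
    active-active edges.  Activity rows naming unknown vertices are
    ignored with a warning, base vertices missing from the table count as
    inactive everywhere.
    """
    ids = [str(v) for v in base.vertex_ids]
    unknown = [v for v in activity.index if v not in set(ids)]
    if unknown:
        logger.warning(
            "ignoring %d activity rows for vertices absent from the base "
            "network (e.g. %s)", len(unknown), unknown[:3],
        )
    snaps = []
    for col in activity.columns:
        active = np.zeros(len(ids), dtype=bool)
        for i, v in enumerate(ids):
            if v in activity.index:
                active[i] = activity.loc[v, col] >= threshold
        if not active.any():
            logger.warning("snapshot %r has no active vertices", col)
        A = base.adjacency * np.outer(active, active)
        snaps.append(Snapshot(base.vertex_ids, A, active))
    return SnapshotSeries(snaps, couplings or [])


def grid_couplings(
    n_rows: int, n_cols: int, axis: str = "both"
) -> list[tuple[int, int]]:
    """Couplings for snapshots laid out on a rows-by-columns grid.

    Snapshot index is ``row * n_cols + col`` (row-major).  ``axis`` selects
    which adjacencies are coupled: ``"cols"`` links consecutive columns
    within a row (e.g. developmental stages within a tissue), ``"rows"``
    links consecutive rows within a column, ``"both"`` links all
    orthogonally adjacent cells.
    """
    if axis not in {"rows", "cols", "both"}:
        raise ValueError("axis must be 'rows', 'cols' or 'both'")
    pairs = []
    for r in range(n_rows):
        for c in range(n_cols):
            t = r * n_cols + c
            if axis in {"cols", "both"} and c + 1 < n_cols:
                pairs.append((t, t + 1))
            if axis in {"rows", "both"} and r + 1 < n_rows:
                pairs.append((t, t + n_cols))
    return pairs


def write_series(
    series: SnapshotSeries, directory: str, name: str = "series"
) -> str:
    """Write per-snapshot edge lists plus a YAML manifest; returns its path."""
    os.makedirs(directory, exist_ok=True)
    entries = []
    for t, snap in enumerate(series.snapshots):
        fname = f"snapshot_{t:02d}.tsv"
        write_edge_list(snap, os.path.join(directory, fname))
        entries.append({"name": f"t{t}", "edges": fname})
    manifest = {
        "snapshots": entries,
        "couplings": [list(c) for c in series.couplings],
    }
    path = os.path.join(directory, f"{name}.yaml")
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return path


def read_series(manifest_path: str) -> SnapshotSeries:
    """Load a snapshot series from a YAML manifest (see :func:`write_series`).

    Snapshots may either point at per-snapshot edge files, or the manifest
    may carry a base edge file plus an activity matrix and threshold, in
    which case the series is built with :func:`build_series`.
    """
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    directory = os.path.dirname(os.path.abspath(manifest_path))
    couplings = [tuple(c) for c in manifest.get("couplings", [])]
    if "base" in manifest:
        base = read_edge_list(os.path.join(directory, manifest["base"]))
        activity = read_activity_matrix(
            os.path.join(directory, manifest["activity"])
        )
        return build_series(
            base, activity, manifest.get("threshold", 1.0), couplings
        )
    snaps = [
        read_edge_list(os.path.join(directory, entry["edges"]))
        for entry in manifest["snapshots"]
    ]
    # align every snapshot onto the union vertex set so ids stay global
    universe = sorted({v for s in snaps for v in s.vertex_ids})
    aligned = []
    for s in snaps:
        active = np.array([v in set(s.vertex_ids) for v in universe])
        A = np.zeros((len(universe), len(universe)), dtype=np.int8)
        index = {v: i for i, v in enumerate(universe)}
        iu, ju = np.nonzero(np.triu(s.adjacency, k=1))
        for i, j in zip(iu, ju):
            a, b = index[s.vertex_ids[i]], index[s.vertex_ids[j]]
            A[a, b] = A[b, a] = 1
        aligned.append(Snapshot(tuple(universe), A, active))
    return SnapshotSeries(aligned, couplings)
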