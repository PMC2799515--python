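"""Seeded planted-partition generators for static and dynamic benchmarks.

The static benchmark draws a planted partition whose group count and group
sizes are themselves random (5-10 groups of 5-10 vertices), with within-
and between-group edge probabilities drawn from configurable ranges.  The
dynamic benchmark evolves 30 vertices in 5 groups: each snapshot draws a
fresh planted-partition edge set, then every vertex independently switches
to one of the other groups with probability ``pswitch``, so group sizes
drift over time while the planted labels stay known.

Presets
-------
``marginal``
    Nearly overlapping ranges (Pwithin 0.05-0.1, Pbetween 0.05-0.08,
    rejecting draws with Pwithin <= Pbetween), so recovery is
    intentionally marginal.
``contrast``
    Pwithin = 0.5, Pbetween = 0.05 — a separable hard-contrast regime used
    for recovery benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import Snapshot, SnapshotSeries

PRESETS: dict[str, dict] = {
    "marginal": {
        "pwithin_range": (0.05, 0.1),
        "pbetween_range": (0.05, 0.08),
    },
    "contrast": {
        "pwithin_range": (0.5, 0.5),
        "pbetween_range": (0.05, 0.05),
    },
}

_MAX_REJECTS = 1000


@dataclass
class PlantedTruth:
    """Ground-truth group labels and the generator parameters behind them.

    ``labels`` is ``(n_vertices,)`` for a static draw and
    ``(T, n_vertices)`` for a dynamic series; entries are 0-based group
    indices aligned with the snapshot vertex order.
    """

    labels: np.ndarray
    params: dict
    seed: int | None

    def labels_at(self, t: int | None = None) -> np.ndarray:
        if self.labels.ndim == 1:
            return self.labels
        if t is None:
            raise ValueError("dynamic truth needs a snapshot index")
        return self.labels[t]


def _vertex_ids(n: int) -> tuple:
    return tuple(f"v{i:03d}" for i in range(n))


def _planted_edges(
    labels: np.ndarray, pwithin: float, pbetween: float,
    rng: np.random.Generator,
) -> np.ndarray:
    n = labels.shape[0]
    same = labels[:, None] == labels[None, :]
    p = np.where(same, pwithin, pbetween)
    upper = np.triu(rng.random((n, n)) < p, k=1)
    return (upper | upper.T).astype(np.int8)


def generate_static(
    n_groups_range: tuple[int, int] = (5, 10),
    group_size_range: tuple[int, int] = (5, 10),
    pwithin_range: tuple[float, float] = PRESETS["marginal"]["pwithin_range"],
    pbetween_range: tuple[float, float] = PRESETS["marginal"]["pbetween_range"],
    seed: int | None = None,
    preset: str | None = None,
) -> tuple[Snapshot, PlantedTruth]:
    """One static planted-partition network with known group labels.

    Draws the group count and per-group sizes uniformly from their ranges,
    then ``(pwithin, pbetween)`` uniformly from theirs, rejecting draws
    with ``pwithin <= pbetween``; edges are independent Bernoulli at the
    within/between probability of each pair.
    """
    if preset is not None:
        pwithin_range = PRESETS[preset]["pwithin_range"]
        pbetween_range = PRESETS[preset]["pbetween_range"]
    rng = np.random.default_rng(seed)
    k = int(rng.integers(n_groups_range[0], n_groups_range[1] + 1))
    sizes = rng.integers(
        group_size_range[0], group_size_range[1] + 1, size=k
    )
    for _ in range(_MAX_REJECTS):
        pw = rng.uniform(*pwithin_range)
        pb = rng.uniform(*pbetween_range)
        if pw > pb:
            break
    else:
        raise ValueError(
            "could not draw pwithin > pbetween from the given ranges"
        )
    labels = np.repeat(np.arange(k), sizes)
    A = _planted_edges(labels, pw, pb, rng)
    snap = Snapshot(_vertex_ids(labels.shape[0]), A)
    truth = PlantedTruth(
        labels=labels,
        params={
            "n_groups": k,
            "sizes": sizes.tolist(),
            "pwithin": pw,
            "pbetween": pb,
        },
        seed=seed,
    )
    return snap, truth


def generate_dynamic(
    n_vertices: int = 30,
    n_groups: int = 5,
    pwithin: float = 0.5,
    pbetween: float = 0.05,
    pswitch: float = 0.05,
    T: int = 15,
    seed: int | None = None,
) -> tuple[SnapshotSeries, PlantedTruth]:
    """A series of fresh planted-partition snapshots with drifting labels.

    Vertices start balanced across groups (round-robin).  Each snapshot
    draws independent Bernoulli edges from the current labels; afterwards
    every vertex switches, with probability ``pswitch``, to a group chosen
    uniformly among the other ``n_groups - 1``.  All vertices are active
    in every snapshot; couplings are the consecutive pairs ``(t, t+1)``.
    """
    if not (0 <= pswitch <= 1 and 0 <= pwithin <= 1 and 0 <= pbetween <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ids = _vertex_ids(n_vertices)
    labels = np.arange(n_vertices) % n_groups  # balanced round-robin start
    all_labels = np.empty((T, n_vertices), dtype=np.int64)
    snaps = []
    for t in range(T):
        all_labels[t] = labels
        A = _planted_edges(labels, pwithin, pbetween, rng)
        snaps.append(Snapshot(ids, A))
        if t < T - 1:
            switch = rng.random(n_vertices) < pswitch
            labels = labels.copy()
            for i in np.flatnonzero(switch):
                shift = int(rng.integers(1, n_groups))
                labels[i] = (labels[i] + shift) % n_groups
    series = SnapshotSeries(snaps, [(t, t + 1) for t in range(T - 1)])
    truth = PlantedTruth(
        labels=all_labels,
        params={
            "n_vertices": n_vertices,
            "n_groups": n_groups,
            "pwithin": pwithin,
            "pbetween": pbetween,
            "pswitch": pswitch,
            "T": T,
        },
        seed=seed,
    )
    return series, truth
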