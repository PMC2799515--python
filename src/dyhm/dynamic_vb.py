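"""Time-constrained mean-field inference over a coupled snapshot series.

The dynamic model keeps one set of group-group interaction parameters for
the whole series — module-module edge probabilities are constant over time
and space — while each vertex's leaf membership may drift from snapshot to
snapshot.  The series likelihood is the product of the per-snapshot block
likelihoods under the shared tree parameters, so the Beta posteriors pool
the expected counts of every snapshot; only the membership rows are
per-snapshot.

The smoothness penalty adds ``lambda`` times the KL divergence between a
vertex's membership distributions at coupled snapshots.  The coordinate
update for vertex ``i`` at snapshot ``t`` with ``K`` coupled neighbors
where ``i`` is also active is

    tau_iu(t)  propto  exp( [field_iu(t) + lambda * sum_s log tau_iu(s)]
                            / (1 + lambda * K) )

which recovers the independent static softmax at ``lambda = 0`` (the fit
then dispatches to the static engine, snapshot by snapshot) and the
normalized geometric mean of the neighbors as ``lambda -> inf`` (the
superposed, time-constant fit).

The smoothness weight itself is chosen by a penalized likelihood: the
variational bound minus ``log C(G(G-1), m)``, where ``m`` counts the
distinct directed leaf transitions observed across coupled snapshots —
integrating out a Bernoulli probability per possible transition gives
equal weight to every model with exactly ``m`` observed transitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.special import betaln, gammaln

from .model import expected_counts
from .network import Membership, Snapshot, SnapshotSeries
from .static_vb import (
    TAU_FLOOR,
    VBState,
    _beta_entropy,
    _bisect,
    _spectral_labels,
    _split_weights,
    assignment_field,
    fit_static,
    update_assignment,
    update_tree_params,
)
from .tree import HierTree

#: default smoothness grid for model selection
DEFAULT_LAMBDA_GRID = (0.0, 0.1, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0)


@dataclass
class DynamicState:
    """Fitted state of a coupled series: one VBState per snapshot.

    For ``lam > 0`` all snapshots share one tree (the same object in every
    ``VBState``); each snapshot's ``elbo`` is its additive share of the
    total bound, so ``elbo_sum`` is the series bound in either case.
    ``map_loglik`` is the collapsed marginal likelihood of the
    hard-projected (argmax) assignments — the score used to pick the best
    restart, because the soft bound can rank the degenerate near-uniform
    membership above structured fits on weak-contrast data.
    """

    states: list[VBState]
    lam: float
    series: SnapshotSeries
    objective_trace: np.ndarray = dc_field(default_factory=lambda: np.empty(0))
    converged: bool = True
    seed: int | None = None
    map_loglik: float | None = None

    @property
    def couplings(self) -> list[tuple[int, int]]:
        return self.series.couplings

    @property
    def objective(self) -> float:
        return float(self.objective_trace[-1])

    def elbo_sum(self) -> float:
        return float(sum(s.elbo for s in self.states))


@dataclass
class TransitionTally:
    """Observed distinct directed leaf transitions across coupled snapshots."""

    m: int
    M: int
    transitions: set[tuple[int, int]]

    def __post_init__(self) -> None:
        if not 0 <= self.m <= self.M:
            raise ValueError(f"m={self.m} outside 0..{self.M}")

    @property
    def penalty(self) -> float:
        """``log C(M, m)`` — zero at m = 0 or m = M, maximal between."""
        return float(
            gammaln(self.M + 1)
            - gammaln(self.m + 1)
            - gammaln(self.M - self.m + 1)
        )


def coupled_assignment_update(
    vertex, t: int, state: DynamicState
) -> np.ndarray:
    """Smoothness-coupled membership update of one vertex at one snapshot.

    Mixes the snapshot's own assignment field with the log-memberships of
    the vertex at coupled snapshots where it is also active; does not
    mutate ``state``.  At ``lam = 0`` this is exactly the static softmax
    update of the field.
    """
    series = state.series
    snap = series[t]
    mem_t = state.states[t].membership
    if vertex not in mem_t.vertex_ids:
        raise ValueError(f"vertex {vertex!r} is not active at snapshot {t}")
    f = assignment_field(vertex, snap, mem_t, state.states[t].tree)
    lam = state.lam
    coupling = np.zeros_like(f)
    K = 0
    for s in series.neighbors(t):
        mem_s = state.states[s].membership
        if vertex in mem_s.vertex_ids:
            coupling += np.log(np.clip(mem_s.row(vertex), TAU_FLOOR, None))
            K += 1
    return update_assignment((f + lam * coupling) / (1.0 + lam * K))


class _SeriesProblem:
    """Precomputed arrays and bound bookkeeping for one coupled series."""

    def __init__(self, series: SnapshotSeries, depth: int, prior):
        self.series = series
        self.depth = depth
        self.prior = prior
        self.ids, self.adjs, self.idx = [], [], []
        for snap in series.snapshots:
            i, A = snap.active_subgraph()
            self.ids.append(i)
            self.adjs.append(A)
            self.idx.append({v: k for k, v in enumerate(i)})
        self.shared = {}
        for t, s in series.couplings:
            common = [v for v in self.ids[t] if v in self.idx[s]]
            it = np.array([self.idx[t][v] for v in common], dtype=np.intp)
            js = np.array([self.idx[s][v] for v in common], dtype=np.intp)
            self.shared[(t, s)] = (it, js)
            self.shared[(s, t)] = (js, it)
        # per snapshot: list of (neighbor, own-rows, neighbor-rows)
        self.nbr = [[] for _ in series.snapshots]
        for t in range(len(series)):
            for s in series.neighbors(t):
                it, js = self.shared[(t, s)]
                self.nbr[t].append((s, it, js))
        self.universe = sorted({v for i in self.ids for v in i}, key=str)
        self.snaps_local = [
            Snapshot(tuple(range(A.shape[0])), A) for A in self.adjs
        ]

    def pooled_stats(self, taus, tree):
        """Per-snapshot expected counts and their pooled sums."""
        per = [
            expected_counts(
                self.snaps_local[t],
                Membership(self.snaps_local[t].vertex_ids, taus[t]),
                tree,
            )
            for t in range(len(taus))
        ]
        E = np.sum([s.e for s in per], axis=0)
        N = np.sum([s.n for s in per], axis=0)
        return per, E, N

    def elbo_shares(self, taus, tree, per=None) -> list[float]:
        """Per-snapshot additive shares of the shared-parameter bound.

        Each share carries its snapshot's expected Bernoulli terms, its
        assignment entropy, and the uniform leaf prior; the tree block
        (Beta prior cross-terms and entropies, counted once because the
        parameters are shared) is spread equally so the shares sum to the
        total bound.  ``per`` may pass precomputed per-snapshot counts.
        """
        a0, b0 = self.prior
        elt, el1 = tree.elog_theta, tree.elog_1m_theta
        if per is None:
            per, _, _ = self.pooled_stats(taus, tree)
        tree_block = float(
            np.sum(
                (a0 - 1) * elt
                + (b0 - 1) * el1
                - betaln(a0, b0)
                + _beta_entropy(tree.a, tree.b)
            )
        )
        T = len(taus)
        shares = []
        for t in range(T):
            like = float(np.sum(per[t].e * elt + per[t].n * el1))
            tt = np.clip(taus[t], TAU_FLOOR, None)
            ent = -float(np.sum(taus[t] * np.log(tt)))
            n_t = taus[t].shape[0]
            shares.append(
                like + ent - n_t * np.log(tree.n_leaves) + tree_block / T
            )
        return shares

    def objective(self, taus, tree, lam, per=None) -> float:
        """Minimized quantity: minus the bound plus the coupling KLs
        (both directions of every coupled pair, shared-active rows only)."""
        J = -float(sum(self.elbo_shares(taus, tree, per)))
        if lam > 0:
            for (t, s), (it, js) in self.shared.items():
                p = np.clip(taus[t][it], TAU_FLOOR, None)
                q = np.clip(taus[s][js], TAU_FLOOR, None)
                J += lam * float(
                    np.sum(taus[t][it] * (np.log(p) - np.log(q)))
                )
        return J


def _descend(
    prob: _SeriesProblem, taus, tree, lam, rng, tol, max_sweeps, trace
) -> tuple[HierTree, bool]:
    """Global coordinate-descent sweeps on the coupled objective.

    One sweep updates the shared tree from pooled counts, then passes the
    snapshots in index order updating memberships with the coupled softmax
    (neighbors read asynchronously).  Each vertex's closed-form proposal is
    kept only if it does not increase that vertex's exact contribution to
    the objective — the closed form minimizes the forward-KL part only, so
    unguarded it can transiently raise the symmetric coupling term; the
    guard makes every sweep exactly non-increasing.  Mutates ``taus``;
    appends the objective after each sweep (the post-sweep objective is
    evaluated from the statistics gathered at the start of the next sweep,
    so counts are computed once per sweep).
    """
    from .model import SufficientStats

    converged = False
    sweeps_done = 0
    for _ in range(max_sweeps):
        per, E, N = prob.pooled_stats(taus, tree)
        if sweeps_done > 0:
            # objective of the state left by the previous sweep, under the
            # tree it was swept with
            trace.append(prob.objective(taus, tree, lam, per))
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol * (
                1 + abs(trace[-1])
            ):
                converged = True
                break
        tree = update_tree_params(SufficientStats(E, N), prob.prior, tree)
        W_edge, W_gap = _split_weights(tree)
        for t in range(len(taus)):
            A, Tt = prob.adjs[t], taus[t]
            colsum = Tt.sum(axis=0)
            logT = np.log(np.maximum(Tt, TAU_FLOOR))
            coup = np.zeros_like(Tt)   # sum over neighbors of log tau
            csum = np.zeros_like(Tt)   # sum over neighbors of tau
            kvec = np.zeros(Tt.shape[0])
            for s, it, js in prob.nbr[t]:
                coup[it] += np.log(np.maximum(taus[s][js], TAU_FLOOR))
                csum[it] += taus[s][js]
                kvec[it] += 1.0
            guard = lam > 0
            for i in rng.permutation(Tt.shape[0]):
                old = Tt[i]
                d = A[i] @ Tt
                m = colsum - old
                f = W_edge @ d + W_gap @ (m - d)
                K = kvec[i]
                arg = (f + lam * coup[i]) / (1.0 + lam * K)
                arg -= arg.max()
                ex = np.exp(arg)
                S = ex.sum()
                new = ex / S
                if guard and K > 0:
                    # vertex i's exact objective contribution:
                    # -f.x + (1+lam K) x.log x - lam L.x - lam c.log x
                    a1 = 1.0 + lam * K
                    ci, Li = csum[i], coup[i]

                    def g(x, lx):
                        return (
                            -(f @ x)
                            + a1 * (x @ lx)
                            - lam * (Li @ x)
                            - lam * (ci @ lx)
                        )

                    log_old = logT[i]
                    log_new = arg - np.log(S)
                    g_old = g(old, log_old)
                    if g(new, log_new) > g_old:
                        # geometric damping toward the current value; keep
                        # the first step that still descends, else stay put
                        for alpha in (0.5, 0.25):
                            mix = (1 - alpha) * log_old + alpha * log_new
                            mix -= mix.max()
                            cand = np.exp(mix)
                            cand /= cand.sum()
                            log_cand = mix - np.log(np.exp(mix).sum())
                            if g(cand, log_cand) <= g_old:
                                new, log_new = cand, log_cand
                                break
                        else:
                            continue
                    logT[i] = log_new
                else:
                    logT[i] = np.log(np.maximum(new, TAU_FLOOR))
                colsum += new - old
                Tt[i] = new
        sweeps_done += 1
    if not converged:
        trace.append(prob.objective(taus, tree, lam))
    return tree, converged


def _split_refine(
    prob: _SeriesProblem, taus, tree, lam, rng, tol, max_sweeps, trace
) -> HierTree:
    """Escape merged-block optima by splitting a leaf across all snapshots.

    A leaf holding two planted groups is a local optimum that neither
    single-vertex moves nor the smoothness coupling can undo.  Each
    multiply-occupied leaf (by pooled majority assignment) is tentatively
    bisected along the Fiedler vector of the pooled adjacency of its
    members, the same bisection applied at every snapshot, and the
    candidate re-descended; it is kept only when the coupled objective
    improves, so the recorded trace stays non-increasing.  Candidate
    descents are capped at 40 sweeps and each round tries at most the
    three largest leaves — candidates only need approximate evaluation,
    and slow-mixing regimes would otherwise dominate the runtime.
    """
    max_sweeps = min(max_sweeps, 40)
    G = tree.n_leaves
    improved = True
    rounds = 0
    while improved and rounds < G:
        improved = False
        rounds += 1
        votes = {v: np.zeros(G) for v in prob.universe}
        for t, Tt in enumerate(taus):
            z = Tt.argmax(axis=1)
            for v, i in prob.idx[t].items():
                votes[v][z[i]] += 1
        major = {v: int(votes[v].argmax()) for v in prob.universe}
        occ = np.zeros(G, dtype=int)
        for v in prob.universe:
            occ[major[v]] += 1
        empty = np.flatnonzero(occ == 0)
        if empty.size == 0:
            break
        for u in np.argsort(-occ)[:3]:
            if occ[u] < 2:
                break
            members = [v for v in prob.universe if major[v] == u]
            pos = {v: k for k, v in enumerate(members)}
            pooled = np.zeros((len(members), len(members)))
            for t, A in enumerate(prob.adjs):
                rows = [
                    (pos[v], prob.idx[t][v])
                    for v in members
                    if v in prob.idx[t]
                ]
                for pv, iv in rows:
                    for pw, jw in rows:
                        pooled[pv, pw] += A[iv, jw]
            side = _bisect(pooled, rng)
            moved = {v for v, s in zip(members, side) if s}
            taus_try = [Tt.copy() for Tt in taus]
            for t, Tt in enumerate(taus_try):
                for v in moved:
                    i = prob.idx[t].get(v)
                    if i is not None:
                        Tt[i] = TAU_FLOOR
                        Tt[i, empty[0]] = 1.0
                        Tt[i] /= Tt[i].sum()
            sub: list[float] = []
            tree_try, _ = _descend(
                prob, taus_try, tree.copy(), lam, rng, tol, max_sweeps, sub
            )
            if sub and sub[-1] < trace[-1] - tol * (1 + abs(trace[-1])):
                for t in range(len(taus)):
                    taus[t][:] = taus_try[t]
                tree = tree_try
                trace.append(sub[-1])
                improved = True
                break
    return tree


def _map_loglik_pooled(prob: _SeriesProblem, taus, tree: HierTree) -> float:
    """Collapsed likelihood of the argmax assignments under the shared tree."""
    from .mcmc import hard_counts
    from .model import SufficientStats, collapsed_log_likelihood

    E = np.zeros(tree.n_nodes)
    N = np.zeros(tree.n_nodes)
    for t in range(len(taus)):
        stats = hard_counts(prob.adjs[t], taus[t].argmax(axis=1), tree)
        E += stats.e
        N += stats.n
    return collapsed_log_likelihood(SufficientStats(E, N), prob.prior)


def fit_dynamic(
    series: SnapshotSeries,
    depth: int,
    lam: float,
    restarts: int = 7,
    seed: int | np.random.SeedSequence | None = None,
    tol: float = 1e-6,
    max_global_sweeps: int = 120,
    prior: tuple[float, float] = (1.0, 1.0),
) -> DynamicState:
    """Coordinate descent on the coupled objective; best restart kept.

    At ``lam = 0`` the objective separates and the fit runs the static
    engine independently per snapshot (bit-identical to
    :func:`~dyhm.static_vb.fit_static` with matched seeds).  For
    ``lam > 0`` every restart starts all snapshots from one hard partition
    of the global vertex universe obtained by hierarchical spectral
    bisection of the pooled adjacency (randomly perturbed after the first
    restart), descends the coupled objective with a shared tree, and runs
    coordinated leaf-split refinement.  Restarts are compared by the
    collapsed likelihood of their hard-projected assignments, which —
    unlike the soft bound — cannot be inflated by the degenerate
    near-uniform membership.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if len(series) == 0:
        raise ValueError("empty snapshot series")
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    if lam == 0.0:
        children = ss.spawn(len(series))
        states = [
            fit_static(
                snap, depth, restarts, child, tol=tol,
                max_sweeps=max_global_sweeps, prior=prior,
            )
            for snap, child in zip(series.snapshots, children)
        ]
        trace = np.array([-sum(s.elbo for s in states)])
        from .mcmc import hard_counts
        from .model import collapsed_log_likelihood

        map_ll = 0.0
        for snap, st in zip(series.snapshots, states):
            _, A = snap.active_subgraph()
            map_ll += collapsed_log_likelihood(
                hard_counts(A, st.membership.tau.argmax(axis=1), st.tree),
                prior,
            )
        return DynamicState(
            states, 0.0, series, trace,
            converged=all(s.converged for s in states),
            seed=seed if isinstance(seed, int) else None,
            map_loglik=map_ll,
        )

    prob = _SeriesProblem(series, depth, prior)
    G = 2**depth
    n_univ = len(prob.universe)
    upos = {v: k for k, v in enumerate(prob.universe)}
    pooled = np.zeros((n_univ, n_univ))
    for t, A in enumerate(prob.adjs):
        rows = np.array([upos[v] for v in prob.ids[t]], dtype=np.intp)
        pooled[np.ix_(rows, rows)] += A
    runs = []
    for r, child in enumerate(ss.spawn(restarts)):
        rng = np.random.default_rng(child)
        z_univ = _spectral_labels(pooled, depth, rng)
        if r > 0:  # perturb for restart diversity; restart 0 is pure spectral
            mask = rng.random(n_univ) < 0.15
            z_univ = z_univ.copy()
            z_univ[mask] = rng.integers(G, size=int(mask.sum()))
        taus = []
        for t in range(len(series)):
            Tt = np.full((len(prob.ids[t]), G), TAU_FLOOR)
            for k, v in enumerate(prob.ids[t]):
                Tt[k, z_univ[upos[v]]] = 1.0
            taus.append(Tt / Tt.sum(axis=1, keepdims=True))
        tree = HierTree(depth, prior)
        trace: list[float] = []
        tree, converged = _descend(
            prob, taus, tree, lam, rng, tol, max_global_sweeps, trace
        )
        runs.append(
            {
                "restart": r,
                "rng": rng,
                "taus": taus,
                "tree": tree,
                "trace": trace,
                "converged": converged,
                "map_ll": _map_loglik_pooled(prob, taus, tree),
            }
        )
    # split-refine only the two most promising runs (a local polish;
    # refining every restart would dominate the runtime)
    runs.sort(key=lambda d: -d["map_ll"])
    for run in runs[:2]:
        if run["converged"]:
            run["tree"] = _split_refine(
                prob, run["taus"], run["tree"], lam, run["rng"], tol,
                max_global_sweeps, run["trace"],
            )
            run["map_ll"] = _map_loglik_pooled(prob, run["taus"], run["tree"])
    win = max(runs, key=lambda d: d["map_ll"])
    taus, tree = win["taus"], win["tree"]
    shares = prob.elbo_shares(taus, tree)
    states = [
        VBState(
            membership=Membership(prob.ids[t], taus[t]),
            tree=tree,
            elbo_trace=np.array([shares[t]]),
            restart_index=win["restart"],
            converged=win["converged"],
            n_sweeps=len(win["trace"]),
        )
        for t in range(len(series))
    ]
    return DynamicState(
        states, lam, series, np.asarray(win["trace"]),
        converged=win["converged"],
        seed=seed if isinstance(seed, int) else None,
        map_loglik=win["map_ll"],
    )


def count_transitions(state: DynamicState) -> TransitionTally:
    """Distinct directed leaf-pair switches across coupled snapshots.

    Each vertex active in both snapshots of a coupling ``(t, s)`` with
    ``t < s`` is hard-assigned by argmax; an ordered pair ``(u_t, u_s)``
    with ``u_t != u_s`` counts once no matter how many vertices or
    couplings exhibit it.  ``M = G(G-1)`` is the number of possible
    directed transitions.
    """
    G = state.states[0].membership.n_leaves
    seen: set[tuple[int, int]] = set()
    labels = [s.membership.hard_labels() for s in state.states]
    index = [
        {v: i for i, v in enumerate(s.membership.vertex_ids)}
        for s in state.states
    ]
    for t, s in state.couplings:
        for v, i in index[t].items():
            j = index[s].get(v)
            if j is None:
                continue
            ut, us = int(labels[t][i]), int(labels[s][j])
            if ut != us:
                seen.add((ut, us))
    return TransitionTally(m=len(seen), M=G * (G - 1), transitions=seen)


def penalized_likelihood(state: DynamicState) -> float:
    """Collapsed likelihood of the fit minus the transition-count penalty.

    ``loglik - log C(G(G-1), m)``: integrating a Bernoulli probability
    over each possible directed transition gives equal weight to every
    model with exactly ``m`` observed transitions (the lambda-independent
    ``log(M+1)`` constant is dropped).  The likelihood term is the
    collapsed marginal likelihood of the hard-projected assignments
    (``map_loglik``) rather than the soft bound: on weak-contrast data the
    soft bound rewards high-entropy degenerate memberships, which would
    make the smoothness selection prefer uninformative fits.
    """
    return state.map_loglik - count_transitions(state).penalty


def select_lambda(
    series: SnapshotSeries,
    depth: int,
    grid=DEFAULT_LAMBDA_GRID,
    restarts: int = 7,
    seed: int | None = None,
    **fit_kwargs,
) -> tuple[float, list[dict]]:
    """Penalized-likelihood search over a smoothness grid.

    Fits the series at every ``lambda`` in ``grid`` (same seed, so restarts
    are comparable), scores each fit by :func:`penalized_likelihood`, and
    returns the argmax together with the full score table (one record per
    ``lambda`` with the fitted state attached).  Ties break toward the
    larger ``lambda``.
    """
    if len(grid) == 0:
        raise ValueError("empty lambda grid")
    table: list[dict] = []
    best_lam, best_score = None, -np.inf
    for lam in sorted(grid):
        state = fit_dynamic(
            series, depth, lam, restarts=restarts, seed=seed, **fit_kwargs
        )
        tally = count_transitions(state)
        score = state.map_loglik - tally.penalty
        table.append(
            {
                "lambda": lam,
                "elbo_sum": state.elbo_sum(),
                "map_loglik": state.map_loglik,
                "m": tally.m,
                "penalty": tally.penalty,
                "score": score,
                "state": state,
            }
        )
        if score >= best_score:
            best_lam, best_score = lam, score
    return best_lam, table
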