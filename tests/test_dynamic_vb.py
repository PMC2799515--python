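"""Coupled updates, limits, transition counting, and smoothness selection."""

import numpy as np
import pytest

from dyhm import (
    DynamicState,
    HierTree,
    Membership,
    Snapshot,
    SnapshotSeries,
    TransitionTally,
    VBState,
    count_transitions,
    coupled_assignment_update,
    fit_dynamic,
    fit_static,
    generate_dynamic,
    penalized_likelihood,
    select_lambda,
    update_assignment,
)
from dyhm.static_vb import assignment_field


def _state_from_taus(series, taus, lam, depth=1):
    tree = HierTree(depth)
    states = [
        VBState(
            membership=Membership(s.active_vertex_ids, t),
            tree=tree,
            elbo_trace=np.array([0.0]),
        )
        for s, t in zip(series.snapshots, taus)
    ]
    return DynamicState(states, lam, series, np.array([0.0]), map_loglik=0.0)


@pytest.fixture
def tiny_series():
    """Three identical 2-vertex snapshots in a chain."""
    A = np.array([[0, 1], [1, 0]])
    snaps = [Snapshot(("a", "b"), A) for _ in range(3)]
    return SnapshotSeries(snaps, [(0, 1), (1, 2)])


class TestCoupledUpdate:
    def test_lambda_zero_is_static_update(self, tiny_series):
        rng = np.random.default_rng(0)
        taus = [rng.dirichlet(np.ones(2), size=2) for _ in range(3)]
        state = _state_from_taus(tiny_series, taus, lam=0.0)
        out = coupled_assignment_update("a", 1, state)
        f = assignment_field(
            "a", tiny_series[1], state.states[1].membership, state.states[1].tree
        )
        np.testing.assert_allclose(out, update_assignment(f))

    def test_geometric_mean_limit_single_neighbor(self):
        A = np.zeros((2, 2), dtype=int)
        snaps = [Snapshot(("a", "b"), A) for _ in range(2)]
        series = SnapshotSeries(snaps, [(0, 1)])
        taus = [
            np.array([[0.9, 0.1], [0.5, 0.5]]),
            np.array([[0.5, 0.5], [0.5, 0.5]]),
        ]
        state = _state_from_taus(series, taus, lam=1e6)
        out = coupled_assignment_update("a", 1, state)
        np.testing.assert_allclose(out, [0.9, 0.1], atol=1e-4)

    def test_geometric_mean_two_opposed_neighbors(self):
        A = np.zeros((2, 2), dtype=int)
        snaps = [Snapshot(("a", "b"), A) for _ in range(3)]
        series = SnapshotSeries(snaps, [(0, 1), (1, 2)])
        taus = [
            np.array([[0.8, 0.2], [0.5, 0.5]]),
            np.array([[0.5, 0.5], [0.5, 0.5]]),
            np.array([[0.2, 0.8], [0.5, 0.5]]),
        ]
        state = _state_from_taus(series, taus, lam=1e6)
        out = coupled_assignment_update("a", 1, state)
        # normalized geometric mean: sqrt(0.16) on each side -> (0.5, 0.5)
        np.testing.assert_allclose(out, [0.5, 0.5], atol=1e-4)

    def test_inactive_vertex_rejected(self, tiny_series):
        taus = [np.full((2, 2), 0.5) for _ in range(3)]
        state = _state_from_taus(tiny_series, taus, lam=1.0)
        with pytest.raises(ValueError):
            coupled_assignment_update("zz", 0, state)


class TestFitDynamic:
    def test_lambda_zero_bit_identical_to_static(self):
        series, _ = generate_dynamic(T=3, seed=5)
        state = fit_dynamic(series, depth=2, lam=0.0, restarts=2, seed=11)
        ss = np.random.SeedSequence(11)
        children = ss.spawn(3)
        for t, child in enumerate(children):
            ref = fit_static(series[t], depth=2, restarts=2, seed=child)
            np.testing.assert_array_equal(
                state.states[t].membership.tau, ref.membership.tau
            )

    def test_identical_snapshots_time_constant(self, two_cliques):
        snap, labels = two_cliques
        series = SnapshotSeries([snap] * 3, [(0, 1), (1, 2)])
        state = fit_dynamic(series, depth=1, lam=1.0, restarts=3, seed=2)
        for t in (1, 2):
            np.testing.assert_allclose(
                state.states[0].membership.tau,
                state.states[t].membership.tau,
                atol=1e-6,
            )
        assert count_transitions(state).m == 0

    def test_huge_lambda_memberships_constant(self):
        series, _ = generate_dynamic(T=4, pswitch=0.0, seed=3)
        state = fit_dynamic(series, depth=3, lam=1e6, restarts=2, seed=3)
        for t, s in series.couplings:
            diff = np.abs(
                state.states[t].membership.tau - state.states[s].membership.tau
            ).max()
            assert diff <= 1e-3

    def test_no_switching_large_lambda_recovers_truth(self):
        series, truth = generate_dynamic(T=6, pswitch=0.0, seed=4)
        state = fit_dynamic(series, depth=3, lam=4.0, restarts=3, seed=4)
        from dyhm import co_membership, f1_max, pair_scores_and_labels, pr_curve

        f1s = []
        for t in range(6):
            co = co_membership(state.states[t].membership)
            s_, l_ = pair_scores_and_labels(co, truth.labels_at(t))
            p, r = pr_curve(s_, l_)
            f1s.append(f1_max(p, r))
        assert np.mean(f1s) > 0.9

    def test_objective_trace_non_increasing(self):
        series, _ = generate_dynamic(T=5, seed=6)
        state = fit_dynamic(series, depth=3, lam=0.5, restarts=2, seed=6)
        tr = state.objective_trace
        assert np.all(np.diff(tr) < 1e-6 * (1 + np.abs(tr[1:])))

    def test_negative_lambda_rejected(self, tiny_series):
        with pytest.raises(ValueError):
            fit_dynamic(tiny_series, depth=1, lam=-0.5)


class TestTransitions:
    def test_counting_rules(self, tiny_series):
        taus_const = [np.array([[1.0, 0], [0, 1.0]])] * 3
        state = _state_from_taus(tiny_series, taus_const, lam=0.0)
        assert count_transitions(state).m == 0
        # one vertex moves leaf 1 -> 2 across the first coupling
        taus_move = [
            np.array([[1.0, 0], [0, 1.0]]),
            np.array([[0, 1.0], [0, 1.0]]),
            np.array([[0, 1.0], [0, 1.0]]),
        ]
        tally = count_transitions(
            _state_from_taus(tiny_series, taus_move, lam=0.0)
        )
        assert tally.m == 1
        assert tally.transitions == {(1, 2)}
        assert tally.M == 2

    def test_m_bounded_by_M(self):
        series, _ = generate_dynamic(T=6, pswitch=1.0, n_groups=4, seed=9)
        state = fit_dynamic(series, depth=2, lam=0.1, restarts=1, seed=9)
        tally = count_transitions(state)
        assert 0 <= tally.m <= tally.M == 12


class TestPenalizedLikelihood:
    def test_penalty_endpoints_and_example(self):
        assert TransitionTally(0, 56, set()).penalty == 0.0
        assert np.isclose(TransitionTally(56, 56, set()).penalty, 0.0)
        # G=8: log C(56, 5) = log 3,819,816
        assert np.isclose(
            TransitionTally(5, 56, set()).penalty, np.log(3_819_816)
        )
        # interior penalty exceeds both endpoints
        assert TransitionTally(28, 56, set()).penalty > np.log(3_819_816)

    def test_penalized_likelihood_subtracts_penalty(self, tiny_series):
        taus = [np.array([[1.0, 0], [0, 1.0]])] * 3
        state = _state_from_taus(tiny_series, taus, lam=0.0)
        state.map_loglik = -12.5
        assert penalized_likelihood(state) == -12.5  # m = 0 -> no penalty


class TestSelectLambda:
    def test_identical_snapshots_tie_toward_larger_lambda(self, two_cliques):
        snap, _ = two_cliques
        series = SnapshotSeries([snap] * 3, [(0, 1), (1, 2)])
        lam, table = select_lambda(
            series, depth=1, grid=(0.5, 2.0), restarts=2, seed=0
        )
        scores = {r["lambda"]: r["score"] for r in table}
        if np.isclose(scores[0.5], scores[2.0]):
            assert lam == 2.0

    def test_smoothing_selected_on_slow_drift(self):
        """With rare group switching the penalized likelihood prefers a
        smoothed fit over independent snapshots."""
        series, truth = generate_dynamic(T=8, pswitch=0.05, seed=12)
        lam, table = select_lambda(
            series, depth=3, grid=(0.0, 0.5), restarts=3, seed=12
        )
        assert lam > 0

    def test_empty_grid_rejected(self, tiny_series):
        with pytest.raises(ValueError):
            select_lambda(tiny_series, depth=1, grid=())
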