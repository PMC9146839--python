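import math

import numpy as np
import pytest

from grandnet import (
    DegreeEnsembleModel,
    bender_canfield_entropy,
    build_degree_prior,
    build_size_prior,
    hamiltonian_degree,
    marginal_link_prob_degree,
    mh_step_fixed_N,
    mh_step_resize,
    run_chain,
)
from grandnet.degree_ensemble import (
    ConstraintError,
    conditional_link_prob_degree,
    conditional_link_prob_degree_fixed_N,
    initial_state,
)
from grandnet.network import NetworkState


def cycle_model():
    """Delta size prior at 4, all degrees exactly 2: the 4-cycle is feasible."""
    sp = build_size_prior("delta", {"Nbar": 4}, N0=2, Nmax=6)
    dp = build_degree_prior([0, 0, 1.0], m_hat=2, K=2)
    return DegreeEnsembleModel(size_prior=sp, degree_prior=dp)


class TestBenderCanfield:
    def test_single_edge_sequence_has_one_graph(self):
        # degrees (1,1): exactly one matching, so log-count 0
        assert bender_canfield_entropy([1, 1]) == pytest.approx(0.0, abs=1e-12)

    def test_three_node_sequence_counts_self_loop_matchings(self):
        # 4 stubs, node 3 holds two: 3 matchings / 2! stub permutations,
        # including the self-loop pairing - the formula is asymptotic
        assert bender_canfield_entropy([1, 1, 2]) == pytest.approx(
            math.log(3 / 2), rel=1e-12
        )

    def test_symmetric_under_permutation(self, rng):
        deg = [1, 3, 2, 2, 4, 2]
        for _ in range(10):
            perm = rng.permutation(deg)
            assert bender_canfield_entropy(perm) == pytest.approx(
                bender_canfield_entropy(deg), rel=1e-12
            )

    def test_odd_degree_sum_rejected(self):
        with pytest.raises(ConstraintError, match="odd"):
            bender_canfield_entropy([1, 1, 1])


class TestHamiltonian:
    def test_term_by_term_cross_check_on_four_cycle(self):
        model = cycle_model()
        state = NetworkState(4, [(0, 1), (1, 2), (2, 3), (3, 0)])
        # independent evaluation: -ln pi(4) - sum_i ln[p(k_i) k_i!] + ln (2L-1)!!
        expected = 0.0
        for k in [2, 2, 2, 2]:
            expected -= math.log(1.0 * math.factorial(k))
        expected += math.log(7 * 5 * 3 * 1)
        assert hamiltonian_degree(state, model) == pytest.approx(expected, rel=1e-12)

    def test_exactly_invariant_under_relabelling(self, rng):
        model = cycle_model()
        state = NetworkState(4, [(0, 1), (1, 2), (2, 3), (3, 0)])
        h = hamiltonian_degree(state, model)
        for _ in range(50):
            relabelled = state.relabel(rng.permutation(4))
            assert hamiltonian_degree(relabelled, model) == h

    def test_depends_only_on_degree_multiset(self):
        model = cycle_model()
        a = NetworkState(4, [(0, 1), (1, 2), (2, 3), (3, 0)])
        b = NetworkState(4, [(0, 2), (2, 1), (1, 3), (3, 0)])
        assert hamiltonian_degree(a, model) == hamiltonian_degree(b, model)

    def test_constraint_violations_named(self):
        model = cycle_model()
        with pytest.raises(ConstraintError, match="link-count"):
            hamiltonian_degree(NetworkState(4, [(0, 1)]), model)
        sp = build_size_prior("delta", {"Nbar": 4}, N0=2, Nmax=6)
        loose = DegreeEnsembleModel(
            size_prior=sp, degree_prior=build_degree_prior([0, 0.5, 0.5], m_hat=1, K=2)
        )
        # <k> = 1.5 so L(4) = 3: the star has the right link count but a hub
        # of degree 3 > K = 2
        star = NetworkState(4, [(0, 1), (0, 2), (0, 3)])
        with pytest.raises(ConstraintError, match="max-degree"):
            hamiltonian_degree(star, loose)


class TestFixedNMoves:
    def test_conservation_of_links_and_bounds(self, rng):
        sp = build_size_prior("delta", {"Nbar": 30}, N0=5, Nmax=40)
        dp = build_degree_prior(np.exp(-np.arange(7) / 2.0), m_hat=1, K=6)
        model = DegreeEnsembleModel(size_prior=sp, degree_prior=dp)
        state = initial_state(model, rng, 30)
        L = state.n_edges
        table = model.degree_term_table()
        for _ in range(2000):
            mh_step_fixed_N(state, model, rng, table)
            assert state.n_edges == L
        deg = state.degrees
        assert deg.min() >= 1 and deg.max() <= 6

    def test_empty_graph_skips_without_error(self, rng):
        sp = build_size_prior("delta", {"Nbar": 4}, N0=2, Nmax=6)
        dp = build_degree_prior([1.0], m_hat=0, K=0)
        model = DegreeEnsembleModel(size_prior=sp, degree_prior=dp)
        state = NetworkState(4)
        _, accepted, _ = mh_step_fixed_N(state, model, rng)
        assert not accepted and state.n_edges == 0


class TestResizeMoves:
    def test_delta_prior_keeps_N_constant(self, rng):
        model = cycle_model()
        state = NetworkState(4, [(0, 1), (1, 2), (2, 3), (3, 0)])
        for _ in range(100):
            state, accepted = mh_step_resize(state, model, rng)
            assert not accepted
            assert state.N == 4

    def test_proposal_to_N0_rejected(self, rng):
        # N = N0 + 1: downward proposals must always be rejected
        sp = build_size_prior("uniform", N0=9, Nmax=12)
        dp = build_degree_prior([0.3, 0.4, 0.3], m_hat=0, K=2)
        model = DegreeEnsembleModel(size_prior=sp, degree_prior=dp)
        state = initial_state(model, rng, 10)
        for _ in range(200):
            before = state.N
            state, accepted = mh_step_resize(state, model, rng)
            assert state.N > 9
            if accepted:
                assert state.n_edges == model.target_link_count(state.N)
                deg = state.degrees
                assert deg.min() >= 0 and deg.max() <= 2
            else:
                assert state.N == before

    def test_rejection_rolls_back_exactly(self, rng):
        model = cycle_model()  # delta prior: every resize is rejected early
        state = NetworkState(4, [(0, 1), (1, 2), (2, 3), (3, 0)])
        snapshot = (state.N, set(state.edges))
        for _ in range(50):
            state, _ = mh_step_resize(state, model, rng)
        assert (state.N, set(state.edges)) == snapshot


class TestRunChain:
    def test_same_seed_reproduces_trace(self, fig_degree_model):
        r1 = run_chain(fig_degree_model, 3000, 10, np.random.default_rng(5))
        r2 = run_chain(fig_degree_model, 3000, 10, np.random.default_rng(5))
        assert np.array_equal(r1.N_trace, r2.N_trace)
        assert r1.final_state.edges == r2.final_state.edges

    def test_delta_size_prior_gives_constant_trace(self, rng):
        sp = build_size_prior("delta", {"Nbar": 20}, N0=5, Nmax=30)
        dp = build_degree_prior([0.2, 0.5, 0.3], m_hat=0, K=2)
        model = DegreeEnsembleModel(size_prior=sp, degree_prior=dp)
        res = run_chain(model, 2000, 10, rng, record_every=1)
        assert np.all(res.N_trace == 20)


class TestMarginals:
    def test_delta_prior_collapse(self):
        sp = build_size_prior("delta", {"Nbar": 200}, N0=50, Nmax=400)
        dp = build_degree_prior([0, 0.5, 0, 0.25, 0.25], m_hat=1, K=4)
        model = DegreeEnsembleModel(size_prior=sp, degree_prior=dp)
        assert marginal_link_prob_degree(model) == pytest.approx(
            model.mean_degree / 200, rel=1e-12
        )

    def test_two_point_prior_arithmetic(self):
        sp = build_size_prior("table", {"probs": [0.5] + [0] * 99 + [0.5]}, N0=100, Nmax=200)
        dp = build_degree_prior([0, 0, 0, 0, 1.0], m_hat=4, K=4)  # <k> = 4
        model = DegreeEnsembleModel(size_prior=sp, degree_prior=dp)
        assert marginal_link_prob_degree(model) == pytest.approx(0.03, rel=1e-12)

    def test_fixed_N_uncorrelated_expression(self):
        sp = build_size_prior("delta", {"Nbar": 100}, N0=50, Nmax=150)
        dp = build_degree_prior([0, 0, 1.0], m_hat=2, K=2)  # <k> = 2
        model = DegreeEnsembleModel(size_prior=sp, degree_prior=dp)
        assert conditional_link_prob_degree_fixed_N(model, 2, 2, 100) == pytest.approx(
            0.02, rel=1e-12
        )

    def test_marginal_consistency_identities(self, fig_degree_model):
        model = fig_degree_model
        sp, dp = model.size_prior, model.degree_prior
        pij = marginal_link_prob_degree(model)
        # averaging the degree-conditional marginal over p(k) p(k') recovers p_ij
        acc = 0.0
        for k, pk in zip(dp.support, dp.probabilities):
            for kp, pkp in zip(dp.support, dp.probabilities):
                acc += pk * pkp * conditional_link_prob_degree(model, k, kp)
        assert acc == pytest.approx(pij, abs=1e-12)
        # averaging the fixed-N expression over pi(N) recovers the conditional
        acc_N = sum(
            w * conditional_link_prob_degree_fixed_N(model, 2, 3, int(N))
            for N, w in zip(sp.support, sp.weights)
        )
        assert acc_N == pytest.approx(conditional_link_prob_degree(model, 2, 3), abs=1e-12)

    def test_aldous_hoover_behaviour(self, fig_degree_model):
        # conditional at fixed N vanishes as N grows; the mixture stays positive
        vals = [
            conditional_link_prob_degree_fixed_N(fig_degree_model, 3, 3, N)
            for N in (10**2, 10**4, 10**6)
        ]
        assert vals[0] > vals[1] > vals[2]
        assert vals[2] < 1e-5
        assert marginal_link_prob_degree(fig_degree_model) > 1e-3
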