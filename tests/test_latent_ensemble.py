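import math

import numpy as np
import pytest

from grandnet import (
    LatentEnsembleModel,
    build_latent_prior,
    build_size_prior,
    generate,
    hamiltonian_latent,
    link_prob,
    marginal_link_prob_latent,
    shannon_entropy_fixed,
)
from grandnet.latent_ensemble import (
    LatentNetworkDraw,
    conditional_link_prob_latent,
    conditional_link_prob_latent_fixed_N,
)
from grandnet.network import NetworkState


def bernoulli_entropy(p):
    return -(p * math.log(p) + (1 - p) * math.log(1 - p))


class TestLinkProb:
    def test_zero_latent_disconnects(self):
        assert link_prob(0.0, 3.0, 50) == 0.0

    def test_unit_latents(self):
        assert link_prob(1.0, 1.0, 99) == pytest.approx(0.01, rel=1e-12)

    def test_monotone_in_product_and_size(self):
        ps = [link_prob(t, 1.0, 100) for t in np.linspace(0, 5, 20)]
        assert all(b >= a for a, b in zip(ps, ps[1:]))
        qs = [link_prob(2.0, 2.0, N) for N in (10, 100, 1000)]
        assert qs[0] > qs[1] > qs[2]

    def test_never_exceeds_one(self):
        assert link_prob(1e6, 1e6, 2) <= 1.0


class TestGenerate:
    def test_all_mass_at_zero_gives_empty_graphs(self, rng):
        model = LatentEnsembleModel(
            size_prior=build_size_prior("delta", {"Nbar": 30}, N0=5, Nmax=40),
            latent_prior=build_latent_prior([0.0], [1.0]),
        )
        for _ in range(5):
            assert generate(model, rng).state.n_edges == 0

    def test_link_frequencies_match_kernel(self, rng):
        # pooled pair frequencies per (theta, theta') cell vs the kernel
        N = 40
        model = LatentEnsembleModel(
            size_prior=build_size_prior("delta", {"Nbar": N}, N0=5, Nmax=50),
            latent_prior=build_latent_prior([1.0, 4.0], [0.5, 0.5]),
        )
        hits = {}
        totals = {}
        for _ in range(300):
            draw = generate(model, rng)
            th = draw.theta
            iu, ju = np.triu_indices(N, k=1)
            for key in ((1.0, 1.0), (1.0, 4.0), (4.0, 4.0)):
                mask = (np.minimum(th[iu], th[ju]) == key[0]) & (
                    np.maximum(th[iu], th[ju]) == key[1]
                )
                totals[key] = totals.get(key, 0) + int(mask.sum())
                linked = sum(
                    1
                    for i, j in zip(iu[mask], ju[mask])
                    if draw.state.has_edge(int(i), int(j))
                )
                hits[key] = hits.get(key, 0) + linked
        for key in totals:
            p = link_prob(key[0], key[1], N)
            n = totals[key]
            assert n > 1000
            sigma = math.sqrt(n * p * (1 - p))
            assert abs(hits[key] - n * p) < 3 * sigma

    def test_mean_degree_matches_direct_sum(self, rng):
        N = 50
        prior = build_latent_prior([0.5, 2.0, 5.0], [0.5, 0.3, 0.2])
        model = LatentEnsembleModel(
            size_prior=build_size_prior("delta", {"Nbar": N}, N0=5, Nmax=60),
            latent_prior=prior,
        )
        target_theta = 5.0
        expected = (N - 1) * sum(
            p * link_prob(target_theta, t, N)
            for t, p in zip(prior.grid, prior.probabilities)
        )
        degs = []
        for _ in range(400):
            draw = generate(model, rng)
            sel = np.flatnonzero(draw.theta == target_theta)
            degs.extend(draw.state.degrees[sel].tolist())
        n = len(degs)
        assert n > 500
        sem = np.std(degs, ddof=1) / math.sqrt(n)
        assert abs(np.mean(degs) - expected) < 3 * sem


class TestHamiltonian:
    def model(self):
        return LatentEnsembleModel(
            size_prior=build_size_prior("delta", {"Nbar": 4}, N0=2, Nmax=6),
            latent_prior=build_latent_prior([0.0, 1.0, 2.0], [0.2, 0.5, 0.3]),
        )

    def test_matches_hierarchical_product_term_by_term(self):
        model = self.model()
        theta = np.array([1.0, 2.0, 1.0, 0.0])
        state = NetworkState(4, [(0, 1), (1, 2)])
        draw = LatentNetworkDraw(N=4, theta=theta, state=state)
        # independent evaluation of -ln[pi(N) prod p(theta_i) prod Bernoulli]
        expected = 0.0  # delta prior: ln pi = 0
        for t in theta:
            expected -= math.log({0.0: 0.2, 1.0: 0.5, 2.0: 0.3}[t])
        for i in range(4):
            for j in range(i + 1, 4):
                x = theta[i] * theta[j] / 4
                p = x / (1 + x)
                a = state.has_edge(i, j)
                expected -= math.log(p) if a else math.log(1 - p)
        assert hamiltonian_latent(draw, model) == pytest.approx(expected, rel=1e-12)

    def test_invariant_under_paired_permutation(self, rng):
        model = self.model()
        theta = np.array([1.0, 2.0, 1.0, 2.0])
        state = NetworkState(4, [(0, 1), (2, 3), (0, 3)])
        h = hamiltonian_latent(LatentNetworkDraw(4, theta, state), model)
        for _ in range(50):
            perm = rng.permutation(4)
            inv = np.argsort(perm)
            relabelled = state.relabel(perm)
            h2 = hamiltonian_latent(
                LatentNetworkDraw(4, theta[inv], relabelled), model
            )
            assert h2 == pytest.approx(h, rel=1e-12)

    def test_empty_graph_all_zero_latents(self):
        model = self.model()
        draw = LatentNetworkDraw(4, np.zeros(4), NetworkState(4))
        assert hamiltonian_latent(draw, model) == pytest.approx(
            -4 * math.log(0.2), rel=1e-12
        )

    def test_impossible_configuration_flags_infinity(self):
        model = self.model()
        draw = LatentNetworkDraw(4, np.zeros(4), NetworkState(4, [(0, 1)]))
        assert hamiltonian_latent(draw, model) == math.inf


class TestShannonEntropy:
    def test_zero_latents_zero_entropy(self):
        assert shannon_entropy_fixed(np.zeros(5), 5) == 0.0

    def test_half_probability_pair(self):
        # theta_i theta_j / N = 1 makes the pair a fair coin
        assert shannon_entropy_fixed(np.array([1.0, 2.0]), 2) == pytest.approx(
            math.log(2), rel=1e-12
        )

    def test_three_unit_latents(self):
        val = shannon_entropy_fixed(np.ones(3), 3)
        assert val == pytest.approx(3 * bernoulli_entropy(0.25), rel=1e-12)

    def test_bounded_by_pair_count_times_ln2(self):
        theta = np.array([0.5, 1.0, 2.0, 4.0])
        val = shannon_entropy_fixed(theta, 4)
        assert 0 <= val <= 6 * math.log(2)


class TestMarginals:
    def two_point_model(self):
        return LatentEnsembleModel(
            size_prior=build_size_prior("table", {"probs": [0.5, 0.5]}, N0=99, Nmax=100),
            latent_prior=build_latent_prior([0.0, 1.0, 3.0], [0.2, 0.5, 0.3]),
        )

    def test_zero_latent_marginals_vanish(self):
        model = self.two_point_model()
        assert conditional_link_prob_latent(model, 0.0, 2.0) == 0.0
        assert conditional_link_prob_latent_fixed_N(0.0, 2.0, 100) == 0.0

    def test_delta_prior_collapse(self):
        model = LatentEnsembleModel(
            size_prior=build_size_prior("delta", {"Nbar": 99}, N0=50, Nmax=150),
            latent_prior=build_latent_prior([1.0, 2.0], [0.6, 0.4]),
        )
        direct = sum(
            p * q * link_prob(t, tp, 99)
            for t, p in zip([1.0, 2.0], [0.6, 0.4])
            for tp, q in zip([1.0, 2.0], [0.6, 0.4])
        )
        assert marginal_link_prob_latent(model) == pytest.approx(direct, rel=1e-12)

    def test_pair_conditional_at_unit_latents(self):
        model = LatentEnsembleModel(
            size_prior=build_size_prior("delta", {"Nbar": 99}, N0=50, Nmax=150),
            latent_prior=build_latent_prior([1.0], [1.0]),
        )
        assert conditional_link_prob_latent(model, 1.0, 1.0) == pytest.approx(
            0.01, rel=1e-12
        )

    def test_pair_conditional_equals_kernel_averaged_over_sizes(self):
        model = self.two_point_model()
        for t, tp in [(1.0, 1.0), (1.0, 3.0), (3.0, 3.0)]:
            avg = sum(
                w * conditional_link_prob_latent_fixed_N(t, tp, int(N))
                for N, w in zip(model.size_prior.support, model.size_prior.weights)
            )
            assert conditional_link_prob_latent(model, t, tp) == pytest.approx(
                avg, abs=1e-12
            )

    def test_aldous_hoover_behaviour(self):
        model = self.two_point_model()
        assert marginal_link_prob_latent(model) > 0
        vals = [conditional_link_prob_latent_fixed_N(2.0, 2.0, N) for N in (10, 10**4, 10**7)]
        assert vals[0] > vals[1] > vals[2] and vals[2] < 1e-5
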