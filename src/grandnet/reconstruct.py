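"""Sampling full networks consistent with an observed induced subgraph.

Degree route: given posterior draws of the true degrees (k for sampled
nodes, q for unsampled nodes), the hidden part of the network is a uniform
constrained stub matching — extra stubs of sampled nodes pair only with
unsampled stubs (a new sampled-sampled link would contradict the induced
subgraph), and the remaining unsampled stubs pair among themselves.

Latent route: unsampled nodes get latent values from the prior (their
posterior is the prior) and every unobserved pair is linked independently
with the Bernoulli kernel.
"""

from __future__ import annotations

import numpy as np

from .latent_ensemble import LatentEnsembleModel, link_prob
from .network import NetworkState, ObservedSubgraph
from .priors import DegreePrior, LatentPrior

__all__ = [
    "ReconstructionError",
    "reconstruct_degree",
    "reconstruct_latent",
    "sample_degree_completion",
]


class ReconstructionError(RuntimeError):
    """No valid stub matching found within the attempt budget."""


def _attempt_matching(observed, N, extra, q, rng):
    """One random constrained stub matching; returns a NetworkState or None."""
    N_hat = observed.N_hat
    s_stubs = np.repeat(np.arange(N_hat), extra)
    u_stubs = np.repeat(np.arange(N_hat, N), q)
    M = len(s_stubs)
    state = NetworkState(N, observed.graph.edges)
    u_perm = rng.permutation(len(u_stubs))
    chosen = u_stubs[u_perm[:M]]
    rest = u_stubs[u_perm[M:]]
    s_perm = rng.permutation(M)
    for si, uj in zip(s_stubs[s_perm], chosen):
        si, uj = int(si), int(uj)
        if state.has_edge(si, uj):
            return None
        state.add_edge(si, uj)
    rest = rest[rng.permutation(len(rest))]
    for a, b in rest.reshape(-1, 2):
        a, b = int(a), int(b)
        if a == b or state.has_edge(a, b):
            return None
        state.add_edge(a, b)
    return state


def _repair_matching(observed, N, extra, q, rng, max_swaps=20_000):
    """Greedy build with stub-swap repair, used after plain rejection runs out.

    Colliding stub pairs (x, y) are resolved by picking a random hidden edge
    (a, b), removing it and adding (x, b) and (a, y) instead — a
    degree-preserving swap.  Edges are oriented so every new edge keeps the
    bipartite constraint (no new sampled-sampled links).
    """
    N_hat = observed.N_hat
    state = NetworkState(N, observed.graph.edges)
    s_stubs = np.repeat(np.arange(N_hat), extra)
    u_stubs = np.repeat(np.arange(N_hat, N), q)
    M = len(s_stubs)
    u_perm = rng.permutation(len(u_stubs))
    hidden: list[tuple[int, int]] = []
    bad: list[tuple[int, int]] = []  # (x, y): y is always unsampled

    def place(x: int, y: int) -> None:
        if x == y or state.has_edge(x, y):
            bad.append((x, y))
        else:
            state.add_edge(x, y)
            hidden.append((x, y))

    for si, uj in zip(s_stubs[rng.permutation(M)], u_stubs[u_perm[:M]]):
        place(int(si), int(uj))
    rest = u_stubs[u_perm[M:]]
    rest = rest[rng.permutation(len(rest))]
    for a, b in rest.reshape(-1, 2):
        place(int(a), int(b))

    swaps = 0
    while bad and swaps < max_swaps and hidden:
        swaps += 1
        x, y = bad[-1]
        idx = int(rng.integers(len(hidden)))
        a, b = hidden[idx]
        # hidden su edges are stored (sampled, unsampled), so b is always a
        # valid partner for a sampled x; y is unsampled, so any a works
        if len({x, y, a, b}) < 4:
            continue
        if state.has_edge(x, b) or state.has_edge(a, y):
            continue
        state.remove_edge(a, b)
        hidden[idx] = hidden[-1]
        hidden.pop()
        state.add_edge(x, b)
        state.add_edge(a, y)
        hidden.append((x, b))
        hidden.append((a, y))
        bad.pop()
    if bad:
        return None
    return state


def reconstruct_degree(
    observed: ObservedSubgraph,
    N: int,
    k,
    q,
    rng: np.random.Generator,
    max_attempts: int = 1000,
) -> NetworkState:
    """A simple graph with degrees (k, q) containing G-hat as induced subgraph.

    Sampled node i gains exactly k_i - kappa_i new links, all to unsampled
    nodes; the unsampled nodes consume the remaining stubs among
    themselves.  Uniform random stub pairing with rejection of
    self-loops/multi-edges (up to ``max_attempts``), then a swap-repair
    pass; persistent infeasibility raises :class:`ReconstructionError`.
    """
    k = np.asarray(k, dtype=int)
    q = np.asarray(q, dtype=int)
    kappa = observed.kappa
    if len(k) != observed.N_hat or len(q) != N - observed.N_hat:
        raise ValueError("degree vectors do not match (N_hat, N - N_hat)")
    extra = k - kappa
    if np.any(extra < 0):
        raise ReconstructionError("k_i < kappa_i: infeasible true degrees")
    M = int(extra.sum())
    Q = int(q.sum())
    if Q < M or (Q - M) % 2 != 0:
        raise ReconstructionError(
            f"stub accounting infeasible: M={M}, Q={Q} (need Q >= M, Q - M even)"
        )
    for _ in range(max_attempts):
        state = _attempt_matching(observed, N, extra, q, rng)
        if state is not None:
            return state
    state = _repair_matching(observed, N, extra, q, rng)
    if state is None or not np.array_equal(
        state.degrees, np.concatenate([k, q])
    ):
        raise ReconstructionError(
            f"no valid constrained matching found after {max_attempts} attempts "
            f"(M={M}, Q={Q}, N={N})"
        )
    return state


def reconstruct_latent(
    observed: ObservedSubgraph,
    N: int,
    theta_sampled,
    rng: np.random.Generator,
    latent_prior: LatentPrior,
) -> NetworkState:
    """Fill in unobserved pairs with the Bernoulli kernel; keep a-hat intact.

    Unsampled nodes draw their latent values from the prior.  Links are
    added for every sampled-unsampled and unsampled-unsampled pair with
    probability p_N(theta_i, theta_j); the observed block is copied
    unchanged.
    """
    theta_sampled = np.asarray(theta_sampled, dtype=float)
    N_hat = observed.N_hat
    if len(theta_sampled) != N_hat:
        raise ValueError("need one theta per sampled node")
    if N < N_hat:
        raise ValueError("N must be >= N_hat")
    phi = latent_prior.sample(rng, size=N - N_hat)
    theta = np.concatenate([theta_sampled, np.atleast_1d(phi)])
    state = NetworkState(N, observed.graph.edges)
    iu, ju = np.triu_indices(N, k=1)
    hidden = ju >= N_hat  # unobserved pairs: at least one unsampled endpoint
    p = link_prob(theta[iu[hidden]], theta[ju[hidden]], N)
    hit = rng.random(len(p)) < p
    for i, j in zip(iu[hidden][hit].tolist(), ju[hidden][hit].tolist()):
        state.add_edge(i, j)
    return state


def sample_degree_completion(
    observed: ObservedSubgraph,
    node_posteriors,
    prior: DegreePrior,
    N: int,
    M: int,
    Q: int,
    rng: np.random.Generator,
    omega_bar: float = 0.0,
    max_adjust: int = 100_000,
):
    """Draw (k, q) from the per-node posteriors / tilted prior, repaired to exact totals.

    The independent draws land near the conditioning totals; random single
    increments/decrements within each node's support then enforce
    sum(k - kappa) = M and sum(q) = Q exactly.
    """
    kappa = observed.kappa
    k = np.array([d.support[rng.choice(len(d.support), p=d.probabilities)] for d in node_posteriors], dtype=int)
    n_u = N - observed.N_hat
    with np.errstate(divide="ignore"):
        lw = np.log(prior.probabilities) - omega_bar * prior.support
    w = np.exp(lw - lw.max())
    w /= w.sum()
    q = prior.support[rng.choice(len(prior.support), size=n_u, p=w)].astype(int)

    def adjust(vec, lower, upper, target_sum):
        budget = max_adjust
        while vec.sum() != target_sum and budget > 0:
            budget -= 1
            i = int(rng.integers(len(vec)))
            if vec.sum() < target_sum and vec[i] < upper[i]:
                vec[i] += 1
            elif vec.sum() > target_sum and vec[i] > lower[i]:
                vec[i] -= 1
        return vec.sum() == target_sum

    k_lower = np.maximum(kappa, prior.m_hat)
    k_upper = np.full(len(k), prior.K)
    if not adjust(k, k_lower, k_upper, M + int(kappa.sum())):
        raise ReconstructionError("could not match the sampled-degree total M")
    if n_u:
        q_lower = np.full(n_u, prior.m_hat)
        q_upper = np.full(n_u, prior.K)
        if not adjust(q, q_lower, q_upper, Q):
            raise ReconstructionError("could not match the unsampled-degree total Q")
    return k, q
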