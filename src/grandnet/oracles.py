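"""Brute-force oracles and synthetic fixtures.

Everything here is deliberately naive and independent of the closed-form
implementations it is used to check: graph enumeration by explicit edge
subsets, matching counts by recursive pairing of labelled stubs, posteriors
and entropies by exhaustive summation with exact rational combinatorics.
Hard size caps keep the enumerations honest (and fast).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .degree_ensemble import DegreeEnsembleModel, initial_state, mh_step_fixed_N
from .latent_ensemble import LatentEnsembleModel, generate
from .network import NetworkState, ObservedSubgraph, induced_subgraph
from .priors import sample_size

MAX_ENUM_N = 7
MAX_STUBS = 12


class EnumerationCapError(ValueError):
    """Requested enumeration exceeds the hard size cap."""


# ---------------------------------------------------------------------------
# graph enumeration
# ---------------------------------------------------------------------------


def enumerate_graphs(
    N: int,
    L: int | None = None,
    degree_bounds: tuple[int, int] | None = None,
    degree_sequence=None,
    contains: ObservedSubgraph | None = None,
) -> list[NetworkState]:
    """All simple graphs on N labelled nodes satisfying the given constraints.

    ``contains`` requires the subgraph induced on nodes 0..N_hat-1 to equal
    the given observed graph exactly.
    """
    if N > MAX_ENUM_N:
        raise EnumerationCapError(f"enumeration capped at N={MAX_ENUM_N}, got {N}")
    pairs = list(itertools.combinations(range(N), 2))
    if degree_sequence is not None:
        degree_sequence = tuple(int(d) for d in degree_sequence)
        L = sum(degree_sequence) // 2 if L is None else L
    if L is not None:
        subsets = itertools.combinations(pairs, L)
    else:
        subsets = itertools.chain.from_iterable(
            itertools.combinations(pairs, l) for l in range(len(pairs) + 1)
        )
    out = []
    for edges in subsets:
        deg = [0] * N
        for i, j in edges:
            deg[i] += 1
            deg[j] += 1
        if degree_sequence is not None and tuple(deg) != degree_sequence:
            continue
        if degree_bounds is not None:
            lo, hi = degree_bounds
            if any(d < lo or d > hi for d in deg):
                continue
        if contains is not None:
            nh = contains.N_hat
            induced = {e for e in edges if e[0] < nh and e[1] < nh}
            if induced != contains.graph.edges:
                continue
        out.append(NetworkState(N, edges))
    return out


def count_graphs_with_degrees(degrees) -> int:
    """Exact number of simple graphs with the given degree sequence (naive)."""
    return len(enumerate_graphs(len(degrees), degree_sequence=degrees))


# ---------------------------------------------------------------------------
# constrained stub matchings
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MatchingCount:
    """Counts of constrained perfect stub matchings and their projections."""

    matchings: int  # all matchings (self-pairs and parallel pairs allowed)
    simple_matchings: int  # matchings whose projected graph is simple
    distinct_projections: int  # distinct projected multigraphs
    distinct_simple_graphs: int  # distinct simple projected graphs


def enumerate_constrained_matchings(extra_stubs, q_stubs) -> MatchingCount:
    """Count perfect matchings where sampled stubs pair only with unsampled stubs.

    ``extra_stubs[i]`` stubs belong to sampled node i, ``q_stubs[j]`` to
    unsampled node j.  Self-pairs within one unsampled node are permitted at
    stub level (they project to self-loops and are excluded from the simple
    counts).  Parity violations yield zero counts.
    """
    extra_stubs = [int(x) for x in extra_stubs]
    q_stubs = [int(x) for x in q_stubs]
    owners = []  # (node_id, sampled?)
    for i, n in enumerate(extra_stubs):
        owners += [(("s", i))] * n
    for j, n in enumerate(q_stubs):
        owners += [(("u", j))] * n
    total = len(owners)
    if total > MAX_STUBS:
        raise EnumerationCapError(f"stub enumeration capped at {MAX_STUBS} stubs")
    if total % 2 != 0 or sum(extra_stubs) > sum(q_stubs):
        return MatchingCount(0, 0, 0, 0)

    projections: dict[tuple, int] = {}

    def rec(unmatched: list[int], pairs: list[tuple]):
        if not unmatched:
            key = tuple(sorted(pairs))
            projections[key] = projections.get(key, 0) + 1
            return
        a = unmatched[0]
        for pos in range(1, len(unmatched)):
            b = unmatched[pos]
            if owners[a][0] == "s" and owners[b][0] == "s":
                continue
            rec(
                unmatched[1:pos] + unmatched[pos + 1 :],
                pairs + [tuple(sorted((owners[a], owners[b])))],
            )

    rec(list(range(total)), [])
    matchings = sum(projections.values())
    simple_m = 0
    simple_graphs = 0
    for key, cnt in projections.items():
        is_simple = len(set(key)) == len(key) and all(u != v for u, v in key)
        if is_simple:
            simple_m += cnt
            simple_graphs += 1
    return MatchingCount(
        matchings=matchings,
        simple_matchings=simple_m,
        distinct_projections=len(projections),
        distinct_simple_graphs=simple_graphs,
    )


# ---------------------------------------------------------------------------
# exact posteriors (naive, rational arithmetic)
# ---------------------------------------------------------------------------


def _matching_number(x: int) -> int:
    """(x-1)!! for even x >= 0: perfect matchings of x objects."""
    if x % 2 != 0:
        raise ValueError("odd x")
    out = 1
    for v in range(x - 1, 0, -2):
        out *= v
    return out


def exact_size_posterior_degree(
    observed: ObservedSubgraph, model: DegreeEnsembleModel, M: int, N_grid
) -> np.ndarray:
    """P(N | G-hat, M) by exhaustive summation over all (k, q) completions.

    Each term carries pi(N) prod p(k_i) prod p(q_j) times the completion
    probability C(Q,M) M! (Q-M-1)!! prod k_i!/(k_i-kappa_i)! / (2L-1)!!,
    evaluated in exact rational arithmetic.
    """
    kappa = [int(x) for x in observed.kappa]
    N_hat = observed.N_hat
    L_hat = observed.L_hat
    prior = model.degree_prior
    support = [int(s) for s in prior.support[prior.probabilities > 0]]
    pmap = {
        int(s): float(p)
        for s, p in zip(prior.support, prior.probabilities)
        if p > 0
    }
    weights = []
    for N in N_grid:
        N = int(N)
        if (N - N_hat) * len(support) ** max(N - N_hat, 0) > 5_000_000:
            raise EnumerationCapError("exact degree posterior: instance too large")
        L = int(round(model.mean_degree * N / 2.0))
        Q = 2 * L - 2 * L_hat - M
        pi_N = float(np.exp(model.size_prior.log_pmf(np.array([N]))[0]))
        total = 0.0
        if pi_N > 0 and Q >= M >= 0 and (Q - M) % 2 == 0:
            k_ranges = [
                [k for k in support if k >= kap] for kap in kappa
            ]
            q_configs = [
                qs
                for qs in itertools.product(support, repeat=N - N_hat)
                if sum(qs) == Q
            ]
            denom = _matching_number(2 * L)
            for ks in itertools.product(*k_ranges):
                if sum(k - kap for k, kap in zip(ks, kappa)) != M:
                    continue
                comb = Fraction(
                    math.comb(Q, M) * math.factorial(M) * _matching_number(Q - M), denom
                )
                for k, kap in zip(ks, kappa):
                    comb *= Fraction(math.factorial(k), math.factorial(k - kap))
                pk = math.prod(pmap[k] for k in ks)
                for qs in q_configs:
                    total += pk * math.prod(pmap[x] for x in qs) * float(comb)
        weights.append(pi_N * total)
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0:
        raise ValueError("exact posterior vanishes on the whole grid")
    return weights / weights.sum()


def exact_size_posterior_latent(
    observed: ObservedSubgraph, model: LatentEnsembleModel, N_grid
) -> np.ndarray:
    """P(N | G-hat) by exhaustive summation over sampled-node latent configs.

    Uses the exact Bernoulli pair products (no mean-field step): for each
    theta configuration the likelihood is prod_{i<j} p_N^a (1-p_N)^(1-a)
    over observed pairs.
    """
    N_hat = observed.N_hat
    if N_hat > 5:
        raise EnumerationCapError("exact latent posterior capped at N_hat=5")
    grid = model.latent_prior.grid
    probs = model.latent_prior.probabilities
    a = np.zeros((N_hat, N_hat), dtype=bool)
    for i, j in observed.graph.edges:
        a[i, j] = a[j, i] = True
    weights = []
    for N in N_grid:
        N = int(N)
        pi_N = float(np.exp(model.size_prior.log_pmf(np.array([N]))[0]))
        if pi_N <= 0 or N < N_hat:
            weights.append(0.0)
            continue
        total = 0.0
        for combo in itertools.product(range(len(grid)), repeat=N_hat):
            w = math.prod(probs[c] for c in combo)
            if w <= 0:
                continue
            theta = [grid[c] for c in combo]
            like = 1.0
            for i in range(N_hat):
                for j in range(i + 1, N_hat):
                    x = theta[i] * theta[j] / N
                    p = x / (1.0 + x)
                    like *= p if a[i, j] else (1.0 - p)
            total += w * like
        weights.append(pi_N * total)
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0:
        raise ValueError("exact posterior vanishes on the whole grid")
    return weights / weights.sum()


# ---------------------------------------------------------------------------
# exact ensemble entropies (direct -sum P ln P)
# ---------------------------------------------------------------------------


def exact_entropy_degree_ensemble(model: DegreeEnsembleModel) -> float:
    """-sum_G P(G) ln P(G) over the full hierarchical ensemble, enumerated.

    P(G) = pi(N) * P(k(G)|N) / #graphs(k(G)) with P(k|N) the i.i.d. degree
    product conditioned on sum k = 2 L(N) (exactly normalized).
    """
    sp = model.size_prior
    prior = model.degree_prior
    support = [int(s) for s in prior.support[prior.probabilities > 0]]
    pmap = {int(s): float(p) for s, p in zip(prior.support, prior.probabilities) if p > 0}
    S = 0.0
    for N, w in zip(sp.support, sp.weights):
        if w <= 0:
            continue
        N = int(N)
        if N > MAX_ENUM_N:
            raise EnumerationCapError("exact entropy capped at N=7")
        L = model.target_link_count(N)
        seqs = [
            ks
            for ks in itertools.product(support, repeat=N)
            if sum(ks) == 2 * L
        ]
        Z = sum(math.prod(pmap[k] for k in ks) for ks in seqs)
        counts = {}
        for ks in seqs:
            key = tuple(ks)
            counts[key] = count_graphs_with_degrees(ks)
        for ks in seqs:
            c = counts[tuple(ks)]
            if c == 0:
                continue
            p_seq = math.prod(pmap[k] for k in ks) / Z
            pG = float(w) * p_seq / c
            if pG > 0:
                S -= c * pG * math.log(pG)
    return S


def exact_entropy_latent_ensemble(model: LatentEnsembleModel) -> float:
    """-sum P(G, theta, N) ln P(G, theta, N), fully enumerated (tiny models)."""
    sp = model.size_prior
    grid = model.latent_prior.grid
    probs = model.latent_prior.probabilities
    S = 0.0
    for N, w in zip(sp.support, sp.weights):
        if w <= 0:
            continue
        N = int(N)
        if N > 5:
            raise EnumerationCapError("exact latent entropy capped at N=5")
        pairs = list(itertools.combinations(range(N), 2))
        for combo in itertools.product(range(len(grid)), repeat=N):
            p_theta = math.prod(probs[c] for c in combo)
            if p_theta <= 0:
                continue
            theta = [grid[c] for c in combo]
            ps = []
            for i, j in pairs:
                x = theta[i] * theta[j] / N
                ps.append(x / (1.0 + x))
            for mask in range(1 << len(pairs)):
                like = 1.0
                for b, p in enumerate(ps):
                    like *= p if (mask >> b) & 1 else (1.0 - p)
                P = float(w) * p_theta * like
                if P > 0:
                    S -= P * math.log(P)
    return S


# ---------------------------------------------------------------------------
# synthetic fixtures
# ---------------------------------------------------------------------------


@dataclass
class Fixture:
    """Ground truth plus the induced subgraph an observer would see."""

    truth: NetworkState
    params: np.ndarray  # true degrees (degree ensemble) or theta (latent)
    sampled_nodes: np.ndarray
    observed: ObservedSubgraph
    M_true: int  # hidden links incident to sampled nodes
    kind: str


def make_fixture(
    model,
    subset_fraction: float,
    rng: np.random.Generator,
    N: int | None = None,
    mix_steps: int | None = None,
) -> Fixture:
    """Draw a ground-truth network, observe a uniform node subset.

    Degree models use a configuration-model draw (stub matching repaired to
    the exact link count) mixed by fixed-N rewiring steps; latent models use
    the direct generator.  ``subset_fraction`` of the nodes (rounded) are
    sampled uniformly without replacement.
    """
    if not (0 < subset_fraction <= 1):
        raise ValueError("subset_fraction must be in (0, 1]")
    if isinstance(model, DegreeEnsembleModel):
        if N is None:
            N = sample_size(model.size_prior, rng)
        state = initial_state(model, rng, N)
        table = model.degree_term_table()
        if mix_steps is None:
            mix_steps = 5 * state.n_edges
        for _ in range(mix_steps):
            mh_step_fixed_N(state, model, rng, table)
        params = state.degrees.copy()
        kind = "degree"
    elif isinstance(model, LatentEnsembleModel):
        draw = generate(model, rng, N=N)
        state = draw.state
        params = draw.theta
        kind = "latent"
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")
    n_sample = max(1, int(round(subset_fraction * state.N)))
    nodes = np.sort(rng.choice(state.N, size=n_sample, replace=False))
    observed = induced_subgraph(state, nodes)
    true_deg = state.degrees[nodes]
    M_true = int(true_deg.sum() - 2 * observed.L_hat)
    return Fixture(
        truth=state,
        params=params,
        sampled_nodes=nodes,
        observed=observed,
        M_true=M_true,
        kind=kind,
    )
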