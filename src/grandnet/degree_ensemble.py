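"""Grand-canonical ensemble of sparse networks with given degree distribution.

The model is hierarchical: the node count N is drawn from a size prior
pi(N), a degree sequence k is drawn i.i.d. from the (truncated) degree
distribution p(k) subject to sum_i k_i = <k> N, and the graph is uniform
among simple graphs with that degree sequence.  The whole ensemble is
exchangeable: its Hamiltonian

    H(G) = -ln pi(N) - sum_i ln[p(k_i) k_i!] + ln matchings(<k> N)

depends on the graph only through N and the degree multiset (the k_i!
factor is the reciprocal of the per-node stub-permutation count in the
graph-counting formula, so that exp(-H) reproduces
pi(N) prod_i p(k_i) / #graphs(k)).  The number
of graphs with a sparse degree sequence is counted by the Bender-Canfield
asymptotic, ln N(k) = ln matchings(2L) - sum_i ln k_i!, where
matchings(2L) = (2L-1)!! is the number of perfect pairings of the 2L stubs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from ._combinatorics import log_double_factorial, log_factorial
from .network import NetworkState
from .priors import DegreePrior, SizePrior

logger = logging.getLogger(__name__)

__all__ = [
    "DegreeEnsembleModel",
    "ConstraintError",
    "FeasibilityError",
    "bender_canfield_entropy",
    "hamiltonian_degree",
    "mh_step_fixed_N",
    "mh_step_resize",
    "run_chain",
    "initial_state",
    "sample_degree_sequence",
    "entropy_decomposition_degree",
    "marginal_link_prob_degree",
    "conditional_link_prob_degree",
    "conditional_link_prob_degree_fixed_N",
]


class ConstraintError(ValueError):
    """A state violates one of the ensemble's hard constraints."""


class FeasibilityError(ValueError):
    """No state can satisfy the ensemble's hard constraints."""


@dataclass(frozen=True)
class DegreeEnsembleModel:
    size_prior: SizePrior
    degree_prior: DegreePrior
    double_factorial_convention: str = "matching"

    def __post_init__(self):
        # structural cutoff: the uncorrelated-network link probability stays
        # <= 1 only for degrees well below sqrt(<k> N0)
        ks = math.sqrt(self.mean_degree * self.size_prior.N0)
        if self.K > ks:
            logger.warning(
                "maximum degree K=%d exceeds the structural cutoff sqrt(<k> N0)=%.1f; "
                "uncorrelated link probabilities may exceed 1",
                self.K,
                ks,
            )

    @property
    def N0(self) -> int:
        return self.size_prior.N0

    @property
    def m_hat(self) -> int:
        return self.degree_prior.m_hat

    @property
    def K(self) -> int:
        return self.degree_prior.K

    @property
    def mean_degree(self) -> float:
        return self.degree_prior.mean_degree

    def target_link_count(self, N: int) -> int:
        """L(N) = round(<k> N / 2)."""
        return int(round(self.mean_degree * N / 2.0))

    def degree_term_table(self) -> np.ndarray:
        """t[k] = -ln[p(k) k!] for k = 0..K (+inf off-support)."""
        k = np.arange(self.K + 1)
        with np.errstate(divide="ignore"):
            logp = np.log(self.degree_prior.pmf(k))
        return -logp - log_factorial(k)


def bender_canfield_entropy(degrees, model: DegreeEnsembleModel | None = None, *, convention: str | None = None) -> float:
    """Asymptotic log-count of simple graphs with the given sparse degree sequence.

    Sigma_N(k) = ln matchings(2L) - sum_i ln k_i!  with  2L = sum_i k_i.
    """
    if convention is None:
        convention = model.double_factorial_convention if model is not None else "matching"
    degrees = np.asarray(degrees, dtype=int)
    total = int(degrees.sum())
    if total % 2 != 0:
        raise ConstraintError(f"degree sum {total} is odd: no graph exists")
    return float(log_double_factorial(total, convention) - log_factorial(degrees).sum())


def hamiltonian_degree(state: NetworkState, model: DegreeEnsembleModel) -> float:
    """Grand-canonical Hamiltonian; finite only on the constraint manifold.

    Raises :class:`ConstraintError` naming the violated indicator (size
    support, exact link count, minimum or maximum degree) when the state is
    off-manifold.
    """
    N = state.N
    if N < model.N0:
        raise ConstraintError(f"size-support: N={N} < N0={model.N0}")
    lp = model.size_prior.log_pmf(np.array([N]))[0]
    if not np.isfinite(lp):
        raise ConstraintError(f"size-support: pi(N)=0 at N={N}")
    L_target = model.target_link_count(N)
    if state.n_edges != L_target:
        raise ConstraintError(
            f"link-count: |E|={state.n_edges} != L(N)={L_target}"
        )
    deg = state.degrees
    if deg.min(initial=model.m_hat) < model.m_hat:
        raise ConstraintError(f"min-degree: some k_i < m_hat={model.m_hat}")
    if deg.max(initial=model.m_hat) > model.K:
        raise ConstraintError(f"max-degree: some k_i > K={model.K}")
    logp_k = model.degree_prior.log_pmf(deg)
    if not np.all(np.isfinite(logp_k)):
        raise ConstraintError("degree-support: some p(k_i) = 0")
    # summing per-degree-value counts makes the value bitwise invariant
    # under node relabellings (H depends on the degree multiset only)
    counts = np.bincount(deg, minlength=model.K + 1)
    ks = np.arange(model.K + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = counts * (model.degree_prior.log_pmf(ks) + log_factorial(ks))
    return float(
        -lp
        - np.sum(terms[counts > 0])
        + log_double_factorial(2 * L_target, model.double_factorial_convention)
    )


# ---------------------------------------------------------------------------
# degree-sequence and graph construction
# ---------------------------------------------------------------------------


def sample_degree_sequence(model: DegreeEnsembleModel, N: int, rng: np.random.Generator, max_tries: int = 10_000) -> np.ndarray:
    """i.i.d. draw from p(k) with parity repair (one entry resampled until even sum)."""
    deg = model.degree_prior.sample(rng, size=N)
    tries = 0
    while deg.sum() % 2 != 0:
        deg[int(rng.integers(N))] = model.degree_prior.sample(rng)
        tries += 1
        if tries > max_tries:
            raise FeasibilityError("cannot reach even degree sum from this degree prior")
    return deg


def _graph_from_degrees(degrees, rng: np.random.Generator, max_tries: int = 20) -> NetworkState:
    """Simple graph with the exact degree sequence by stub matching.

    Uniform stub pairings are retried on self-loop/multi-edge collisions;
    after the retry budget the last attempt is repaired by degree-preserving
    edge swaps.
    """
    degrees = np.asarray(degrees, dtype=int)
    N = len(degrees)
    stubs = np.repeat(np.arange(N), degrees)
    if len(stubs) % 2 != 0:
        raise FeasibilityError("odd stub count")
    for attempt in range(max_tries):
        perm = rng.permutation(len(stubs))
        pairs = stubs[perm].reshape(-1, 2)
        state = NetworkState(N)
        leftovers = []
        ok = True
        for u, v in pairs:
            u, v = int(u), int(v)
            if u == v or state.has_edge(u, v):
                leftovers.append((u, v))
                ok = False
            else:
                state.add_edge(u, v)
        if ok:
            return state
        if attempt < max_tries - 1:
            continue
        # final attempt: repair collisions by swapping with random good edges
        budget = 200 * (len(leftovers) + 1)
        while leftovers and budget > 0:
            budget -= 1
            u, v = leftovers[-1]
            a, b = state.random_edge(rng)
            # u == v (self-loop leftover) is fine as long as the swap
            # partners are distinct from both endpoints
            if a in (u, v) or b in (u, v):
                continue
            if state.has_edge(u, a) or state.has_edge(v, b):
                continue
            state.remove_edge(a, b)
            state.add_edge(u, a)
            state.add_edge(v, b)
            leftovers.pop()
        if not leftovers:
            return state
    raise FeasibilityError("stub matching failed to produce a simple graph")


def _random_nonedge(state: NetworkState, rng: np.random.Generator, max_tries: int = 10_000):
    N = state.N
    for _ in range(max_tries):
        i = int(rng.integers(N))
        j = int(rng.integers(N))
        if i != j and j not in state.adj[i]:
            return i, j
    return None


def _repair_link_count(
    state: NetworkState,
    target_L: int,
    m_hat: int,
    K: int,
    rng: np.random.Generator,
    max_attempts: int | None = None,
) -> bool:
    """Randomly add/remove links until |E| = target_L with degrees in [m_hat, K].

    Returns False (leaving the state possibly off-manifold; callers must
    then discard it) if the attempt budget is exhausted.
    """
    if max_attempts is None:
        max_attempts = 100 * max(state.N, 1)
    attempts = 0
    deg = state._degrees  # live list view

    def spend() -> bool:
        nonlocal attempts
        attempts += 1
        return attempts <= max_attempts

    # lift deficient nodes to the minimum degree first
    if m_hat > 0:
        while True:
            low = [u for u in range(state.N) if deg[u] < m_hat]
            if not low:
                break
            if not spend():
                return False
            u = low[0]
            v = int(rng.integers(state.N))
            if v == u or v in state.adj[u] or deg[v] >= K:
                continue
            state.add_edge(u, v)
    while state.n_edges != target_L:
        if not spend():
            return False
        if state.n_edges < target_L:
            pair = _random_nonedge(state, rng, max_tries=50)
            if pair is None:
                continue
            i, j = pair
            if deg[i] >= K or deg[j] >= K:
                continue
            state.add_edge(i, j)
        else:
            i, j = state.random_edge(rng)
            if deg[i] <= m_hat or deg[j] <= m_hat:
                continue
            state.remove_edge(i, j)
    return (not deg or (min(deg) >= m_hat and max(deg) <= K))


def initial_state(model: DegreeEnsembleModel, rng: np.random.Generator, N: int | None = None) -> NetworkState:
    """A feasible starting state: stub-matched draw from p(k), repaired to exact L(N)."""
    if model.mean_degree > model.K:
        raise FeasibilityError("<k> exceeds the maximum degree K")
    if N is None:
        from .priors import sample_size

        N = sample_size(model.size_prior, rng)
    for _ in range(50):
        deg = sample_degree_sequence(model, N, rng)
        try:
            state = _graph_from_degrees(deg, rng)
        except FeasibilityError:
            continue
        if _repair_link_count(state, model.target_link_count(N), model.m_hat, model.K, rng):
            return state
    raise FeasibilityError(f"could not construct a feasible initial state at N={N}")


# ---------------------------------------------------------------------------
# Metropolis-Hastings moves
# ---------------------------------------------------------------------------


def mh_step_fixed_N(
    state: NetworkState,
    model: DegreeEnsembleModel,
    rng: np.random.Generator,
    term_table: np.ndarray | None = None,
):
    """One link-rewiring Metropolis step at fixed N (in place).

    Removes a uniformly chosen link (i,j) and inserts a uniformly chosen
    non-link (i',j'), accepting with probability min(1, exp(-dH)).  Because
    H depends only on the degree multiset, dH involves at most four nodes.
    Moves that would push a degree outside [m_hat, K] are rejected.  Returns
    (state, accepted, dH).
    """
    if term_table is None:
        term_table = model.degree_term_table()
    L = state.n_edges
    max_L = state.N * (state.N - 1) // 2
    if L == 0 or L == max_L:
        logger.debug("no valid rewiring proposal (empty or complete graph); skipped")
        return state, False, 0.0
    i, j = state.random_edge(rng)
    pair = _random_nonedge(state, rng)
    if pair is None:
        return state, False, 0.0
    ip, jp = pair
    delta: dict[int, int] = {}
    for node, d in ((i, -1), (j, -1), (ip, 1), (jp, 1)):
        delta[node] = delta.get(node, 0) + d
    deg = state._degrees
    dH = 0.0
    for node, d in delta.items():
        if d == 0:
            continue
        k_old = deg[node]
        k_new = k_old + d
        if k_new < model.m_hat or k_new > model.K:
            return state, False, math.inf
        dH += float(term_table[k_new] - term_table[k_old])
    if not math.isfinite(dH):
        return state, False, math.inf
    if dH > 0 and rng.random() >= math.exp(-dH):
        return state, False, dH
    state.remove_edge(i, j)
    state.add_edge(ip, jp)
    return state, True, dH


def mh_step_resize(
    state: NetworkState,
    model: DegreeEnsembleModel,
    rng: np.random.Generator,
):
    """Propose N -> N +/- 1 with equal probability; accept with min(1, pi(N')/pi(N)).

    On acceptance the link count and degree bounds are restored in place by
    a repair pass (a new node is wired to at least m_hat partners by
    rewiring existing links, then links are added/removed at random until
    |E| = L(N')); if repair fails within the attempt budget all mutations
    are rolled back and the move is rejected.  The proposal has no
    tractable density, so detailed balance across N is approximate; the
    chain is validated empirically against pi(N) mass coverage.  Returns
    (state, accepted).
    """
    N = state.N
    up = bool(rng.integers(2))
    Np = N + 1 if up else N - 1
    if Np <= model.N0 or Np > model.size_prior.Nmax:
        return state, False
    log_ratio = float(
        model.size_prior.log_pmf(np.array([Np]))[0]
        - model.size_prior.log_pmf(np.array([N]))[0]
    )
    if log_ratio < 0 and rng.random() >= math.exp(log_ratio):
        return state, False
    journal = state.start_journal()
    deg = state._degrees
    ok = True
    if up:
        new = state.add_node()
        # give the newcomer m_hat links by rewiring endpoints away from
        # nodes that can spare a stub
        budget = 100 * state.N
        while deg[new] < model.m_hat and budget > 0:
            budget -= 1
            a, b = state.random_edge(rng)
            if deg[a] <= model.m_hat or new in (a, b) or state.has_edge(new, b):
                continue
            state.remove_edge(a, b)
            state.add_edge(new, b)
        ok = deg[new] >= model.m_hat
    else:
        victim = int(rng.integers(N))
        state.swap_nodes(victim, N - 1)
        for u in list(state.adj[N - 1]):
            state.remove_edge(N - 1, u)
        state.pop_node()
    if ok:
        ok = _repair_link_count(
            state, model.target_link_count(Np), model.m_hat, model.K, rng
        )
    if not ok:
        state.undo(journal)
        return state, False
    state.stop_journal()
    return state, True


@dataclass
class ChainResult:
    """Summary of one grand-canonical Metropolis run."""

    final_state: NetworkState
    N_trace: np.ndarray
    move_trace: np.ndarray  # move type at each recorded step: rewire/resize +- accepted
    degree_histogram: np.ndarray  # averaged p(k) over recorded states, k = 0..K
    n_steps: int
    accepted_rewire: int
    accepted_resize: int
    record_every: int
    burn_in: int


def run_chain(
    model: DegreeEnsembleModel,
    n_steps: int,
    resize_period: int = 10,
    rng: np.random.Generator | None = None,
    initial: NetworkState | None = None,
    burn_in: int = 0,
    record_every: int = 10,
    check_every: int = 100_000,
) -> ChainResult:
    """Interleave fixed-N rewiring steps with resize proposals every ``resize_period``.

    Records the N(t) trace and the running degree histogram (post burn-in).
    The incrementally tracked Hamiltonian is re-derived from scratch every
    ``check_every`` steps and must agree within 1e-8 (drift guard).
    """
    if rng is None:
        rng = np.random.default_rng()
    if model.mean_degree > model.K:
        raise FeasibilityError("<k> exceeds the maximum degree K: no feasible states")
    state = initial.copy() if initial is not None else initial_state(model, rng)
    table = model.degree_term_table()
    H_run = hamiltonian_degree(state, model)
    N_trace = []
    move_trace = []
    hist = np.zeros(model.K + 1)
    n_rec = 0
    acc_rewire = 0
    acc_resize = 0
    for t in range(1, n_steps + 1):
        if resize_period and t % resize_period == 0:
            move = "resize"
            state, acc = mh_step_resize(state, model, rng)
            if acc:
                acc_resize += 1
                H_run = hamiltonian_degree(state, model)
        else:
            move = "rewire"
            state, acc, dH = mh_step_fixed_N(state, model, rng, table)
            if acc:
                acc_rewire += 1
                H_run += dH
        if t % record_every == 0:
            N_trace.append(state.N)
            move_trace.append(move if acc else move + "-rejected")
            if t > burn_in:
                counts = np.bincount(state.degrees, minlength=model.K + 1)
                hist += counts / state.N
                n_rec += 1
        if check_every and t % check_every == 0:
            H_full = hamiltonian_degree(state, model)
            if abs(H_full - H_run) > 1e-8:
                raise RuntimeError(
                    f"incremental Hamiltonian drift: {H_run} vs {H_full}"
                )
            H_run = H_full
    if n_rec:
        hist /= n_rec
    return ChainResult(
        final_state=state,
        N_trace=np.asarray(N_trace),
        move_trace=np.asarray(move_trace),
        degree_histogram=hist,
        n_steps=n_steps,
        accepted_rewire=acc_rewire,
        accepted_resize=acc_resize,
        record_every=record_every,
        burn_in=burn_in,
    )


# ---------------------------------------------------------------------------
# entropy decomposition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EntropyDecomposition:
    """Three-level entropy split: size, sequence, and graphs given the sequence."""

    S_size: float
    S_sequence: float
    S_graphs: float
    mc_standard_error: float = 0.0

    @property
    def total(self) -> float:
        return self.S_size + self.S_sequence + self.S_graphs


def _constrained_sequences(support, probs, N, total):
    """Yield (sequence, product-probability) with sum(sequence) == total."""
    support = list(support)
    probs = list(probs)
    seq = []

    def rec(pos, remaining):
        if pos == N:
            if remaining == 0:
                yield tuple(seq), math.prod(
                    probs[support.index(k)] for k in seq
                )
            return
        lo = remaining - max(support) * (N - pos - 1)
        hi = remaining - min(support) * (N - pos - 1)
        for k, p in zip(support, probs):
            if p <= 0 or k > remaining or k < lo or k > hi:
                continue
            seq.append(k)
            yield from rec(pos + 1, remaining - k)
            seq.pop()

    yield from rec(0, total)


def _sample_constrained_sequence(model, N, rng, max_tries=200_000):
    """Draw k ~ p(k)^N conditioned on sum k_i = 2 L(N) by rejection."""
    target = 2 * model.target_link_count(N)
    for _ in range(max_tries):
        deg = model.degree_prior.sample(rng, size=N)
        if int(deg.sum()) == target:
            return deg
    raise FeasibilityError(
        f"rejection sampling of the constrained degree sequence failed at N={N}"
    )


def entropy_decomposition_degree(
    model: DegreeEnsembleModel,
    n_mc: int = 1000,
    rng: np.random.Generator | None = None,
    method: str = "mc",
    degree_term: str = "closed_form",
    log_count_fn=None,
) -> EntropyDecomposition:
    """Decompose the ensemble entropy into size + sequence + graph terms.

    S = S_pi + <S_p(k)>_pi + <Sigma_N(k)>_{pi, P(k|N)}.

    The size term is exact.  With ``degree_term="closed_form"`` the sequence
    term uses the sparse-limit formula sum_N pi(N) * N * H[p(k)]; with
    ``"exact"`` it enumerates the sum-constrained conditional P(k|N)
    (small supports only) and takes its exact entropy.  The graph term is a
    Monte Carlo average of the per-sequence log graph count over draws from
    P(k|N) (``method="mc"``), or an exact enumeration (``method="enumerate"``).
    ``log_count_fn(degrees)`` defaults to the Bender-Canfield asymptotic; an
    exact counter can be injected for oracle comparisons.
    """
    if rng is None:
        rng = np.random.default_rng()
    if log_count_fn is None:
        log_count_fn = lambda deg: bender_canfield_entropy(deg, model)  # noqa: E731
    sp = model.size_prior
    S_size = sp.entropy()
    weights = sp.weights
    Ns = sp.support

    if degree_term not in ("closed_form", "exact"):
        raise ValueError(f"unknown degree_term {degree_term!r}")
    if method not in ("mc", "enumerate"):
        raise ValueError(f"unknown method {method!r}")

    def constrained(N: int):
        total = 2 * model.target_link_count(N)
        seqs = list(
            _constrained_sequences(
                model.degree_prior.support.tolist(),
                model.degree_prior.probabilities.tolist(),
                N,
                total,
            )
        )
        Z = sum(p for _, p in seqs)
        if Z <= 0:
            raise FeasibilityError(f"no degree sequence attains sum {total} at N={N}")
        return seqs, Z

    if degree_term == "closed_form":
        S_seq = float(np.sum(weights * Ns) * model.degree_prior.entropy())
    else:
        # exact entropy of the sum-constrained conditional P(k|N), enumerated
        S_seq = 0.0
        for N, w in zip(Ns, weights):
            if w <= 0:
                continue
            seqs, Z = constrained(int(N))
            S_seq += w * -sum((p / Z) * math.log(p / Z) for _, p in seqs)

    if method == "enumerate":
        S_graphs = 0.0
        for N, w in zip(Ns, weights):
            if w <= 0:
                continue
            seqs, Z = constrained(int(N))
            S_graphs += w * sum(
                (p / Z) * log_count_fn(np.asarray(seq)) for seq, p in seqs
            )
        return EntropyDecomposition(S_size, S_seq, S_graphs, 0.0)

    vals = np.empty(n_mc)
    from .priors import sample_size

    for t in range(n_mc):
        N = sample_size(sp, rng)
        deg = _sample_constrained_sequence(model, N, rng)
        vals[t] = log_count_fn(deg)
    return EntropyDecomposition(
        S_size,
        S_seq,
        float(vals.mean()),
        float(vals.std(ddof=1) / math.sqrt(n_mc)) if n_mc > 1 else math.inf,
    )


# ---------------------------------------------------------------------------
# link marginals
# ---------------------------------------------------------------------------


def marginal_link_prob_degree(model: DegreeEnsembleModel) -> float:
    """p_ij = sum_N pi(N) <k>/N: finite for any proper pi(N)."""
    sp = model.size_prior
    return float(np.sum(sp.weights * model.mean_degree / sp.support))


def conditional_link_prob_degree(model: DegreeEnsembleModel, k: float, k_prime: float) -> float:
    """p(k, k') = k k' sum_N pi(N) / (<k> N)."""
    sp = model.size_prior
    return float(k * k_prime * np.sum(sp.weights / (model.mean_degree * sp.support)))


def conditional_link_prob_degree_fixed_N(
    model: DegreeEnsembleModel, k: float, k_prime: float, N: int, clamp: bool = False
) -> float:
    """p_N(k, k') = k k' / (<k> N), the uncorrelated-network expression."""
    val = k * k_prime / (model.mean_degree * N)
    if val > 1.0:
        logger.warning(
            "p_N(k=%s, k'=%s) = %.3f > 1: structural cutoff violated", k, k_prime, val
        )
        if clamp:
            return 1.0
    return float(val)
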