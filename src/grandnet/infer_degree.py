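"""Bayesian size and degree inference from an induced subgraph (degree route).

Observation model: from a network drawn from the degree-distribution
ensemble, only the subgraph induced by N-hat sampled nodes is seen; kappa_i
is the observed degree of sampled node i and L-hat the observed link count.
The unknowns are the total size N, the true degrees k_i >= kappa_i of the
sampled nodes and the degrees q_j of the unsampled nodes.

Stub accounting ties them together: with M = sum_i (k_i - kappa_i) the
number of hidden links incident to sampled nodes and Q = sum_j q_j the
total degree of unsampled nodes, conservation of stubs forces
Q + M = 2L - 2L-hat with L = <k> N / 2.  The number of completions of the
observed subgraph is a constrained stub-matching count: the M extra stubs
of sampled nodes may pair only with unsampled stubs (any sampled-sampled
pair would have been observed), giving C(Q, M) M! matchings for the
bipartite part times the perfect matchings of the remaining Q - M stubs.

The posterior over N marginalizes the degrees through saddle-point
evaluations of the two constrained sums (exponential tilts whose rates
omega*, omega-bar* solve the stub-count moment conditions).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import gammaln, logsumexp

from ._combinatorics import log_binom, log_double_factorial, log_factorial
from .degree_ensemble import DegreeEnsembleModel, bender_canfield_entropy
from .network import ObservedSubgraph
from .priors import DegreePrior
from .reports import DiscreteDist, PosteriorReport

__all__ = [
    "RangeError",
    "InfeasibleNodeError",
    "log_subgraph_matchings",
    "log_subgraph_count",
    "delta_entropy",
    "degree_posterior",
    "solve_omega",
    "solve_omega_bar",
    "size_posterior_degree",
    "infer_degree_pipeline",
    "scan_M",
]

NEG_INF = float("-inf")


class RangeError(ValueError):
    """Target moment outside the attainable range of the tilted family."""


class InfeasibleNodeError(ValueError):
    """A sampled node admits no true degree consistent with the prior support."""


# ---------------------------------------------------------------------------
# constrained stub-matching combinatorics
# ---------------------------------------------------------------------------


def log_subgraph_matchings(k, q, kappa, convention: str = "matching") -> float:
    """Log count of stub matchings completing the observed subgraph.

    Sampled node i exposes k_i - kappa_i extra stubs, unsampled node j
    exposes q_j stubs; sampled stubs may pair only with unsampled stubs.
    The count is C(Q, M) * M! * matchings(Q - M).  Infeasible inputs
    (k_i < kappa_i, Q < M, odd Q - M) yield -inf rather than an exception.
    """
    k = np.asarray(k, dtype=int)
    q = np.asarray(q, dtype=int)
    kappa = np.asarray(kappa, dtype=int)
    if k.shape != kappa.shape:
        raise ValueError("k and kappa must have the same length (sampled nodes)")
    extra = k - kappa
    if np.any(extra < 0) or np.any(q < 0):
        return NEG_INF
    M = int(extra.sum())
    Q = int(q.sum())
    if Q < M or (Q - M) % 2 != 0:
        return NEG_INF
    return float(
        log_binom(Q, M) + log_factorial(M) + log_double_factorial(Q - M, convention)
    )


def log_subgraph_count(k, q, kappa, convention: str = "matching") -> float:
    """Sigma-hat: asymptotic log number of networks with degrees (k, q) containing G-hat."""
    lm = log_subgraph_matchings(k, q, kappa, convention)
    if lm == NEG_INF:
        return NEG_INF
    k = np.asarray(k, dtype=int)
    q = np.asarray(q, dtype=int)
    kappa = np.asarray(kappa, dtype=int)
    return float(lm - log_factorial(k - kappa).sum() - log_factorial(q).sum())


def delta_entropy(k, q, kappa, model: DegreeEnsembleModel) -> float:
    """Delta-Sigma = Sigma_N(k, q) - Sigma-hat_N(k, q | kappa) >= 0 (asymptotically).

    exp(-Delta-Sigma) is the conditional probability P(G-hat | k, q, N) that a
    uniform graph with degree sequence (k, q) induces exactly G-hat on the
    sampled nodes.  Infeasible completions give +inf (probability zero).
    """
    sigma_hat = log_subgraph_count(k, q, kappa, model.double_factorial_convention)
    if sigma_hat == NEG_INF:
        return math.inf
    all_deg = np.concatenate([np.asarray(k, dtype=int), np.asarray(q, dtype=int)])
    sigma = bender_canfield_entropy(all_deg, model)
    return float(sigma - sigma_hat)


# ---------------------------------------------------------------------------
# tilted degree posteriors and saddle solvers
# ---------------------------------------------------------------------------


def _node_log_weights(prior: DegreePrior, kappa_i: int, omega: float):
    """Unnormalized log weights of the true-degree posterior at tilt omega.

    Support is k in [max(kappa_i, m_hat), K]; weight
    p(k) * k!/(k - kappa_i)! * exp(-omega (k - kappa_i)).  The tilt acts on
    the number of extra stubs so that its moment condition is M directly.
    """
    lo = max(int(kappa_i), prior.m_hat)
    if lo > prior.K:
        raise InfeasibleNodeError(
            f"observed degree kappa={kappa_i} exceeds the maximum degree K={prior.K}"
        )
    ks = np.arange(lo, prior.K + 1)
    with np.errstate(divide="ignore"):
        lw = (
            np.log(prior.pmf(ks))
            + gammaln(ks + 1.0)
            - gammaln(ks - kappa_i + 1.0)
            - omega * (ks - kappa_i)
        )
    return ks, lw


def degree_posterior(kappa_i: int, omega: float, prior: DegreePrior) -> DiscreteDist:
    """Posterior P(k_i | G-hat, omega) ∝ p(k) k!/(k-kappa)! e^(-omega k) on k >= kappa."""
    ks, lw = _node_log_weights(prior, kappa_i, omega)
    finite = np.isfinite(lw)
    if not finite.any():
        raise InfeasibleNodeError(f"empty posterior support for kappa={kappa_i}")
    probs = np.zeros(len(ks))
    probs[finite] = np.exp(lw[finite] - logsumexp(lw[finite]))
    return DiscreteDist(support=ks, probabilities=probs)


def _kappa_groups(kappa) -> dict[int, int]:
    vals, counts = np.unique(np.asarray(kappa, dtype=int), return_counts=True)
    return dict(zip(vals.tolist(), counts.tolist()))


def _M_of_omega(omega: float, groups: dict[int, int], prior: DegreePrior) -> float:
    """Expected total extra stubs sum_i E_omega[k_i - kappa_i]."""
    total = 0.0
    for kap, n in groups.items():
        ks, lw = _node_log_weights(prior, kap, omega)
        finite = np.isfinite(lw)
        lw = lw[finite]
        extras = (ks - kap)[finite]
        w = np.exp(lw - lw.max())
        total += n * float(np.sum(w * extras) / np.sum(w))
    return total


def _extra_range(groups: dict[int, int], prior: DegreePrior) -> tuple[int, int]:
    lo = hi = 0
    for kap, n in groups.items():
        kmin = max(kap, prior.m_hat)
        if kmin > prior.K:
            raise InfeasibleNodeError(f"kappa={kap} exceeds K={prior.K}")
        lo += n * (kmin - kap)
        hi += n * (prior.K - kap)
    return lo, hi


def solve_omega(
    M_target: float,
    kappa,
    prior: DegreePrior,
    tol: float = 1e-10,
    max_iter: int = 400,
) -> float:
    """Root of M(omega) = M_target; M(omega) is strictly decreasing, so unique.

    Brackets are expanded geometrically from [-1, 1]; bisection stops when
    the moment residual drops below ``tol``.
    """
    groups = _kappa_groups(kappa)
    lo_att, hi_att = _extra_range(groups, prior)
    if lo_att == hi_att:
        if abs(M_target - lo_att) <= tol:
            return 0.0
        raise RangeError(
            f"degenerate tilt family: M(omega) = {lo_att} cannot reach {M_target}"
        )
    if not (lo_att < M_target < hi_att):
        raise RangeError(
            f"M={M_target} outside the attainable open interval ({lo_att}, {hi_att})"
        )
    lo, hi = -1.0, 1.0
    for _ in range(200):
        if _M_of_omega(lo, groups, prior) > M_target:
            break
        lo *= 2.0
    for _ in range(200):
        if _M_of_omega(hi, groups, prior) < M_target:
            break
        hi *= 2.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f = _M_of_omega(mid, groups, prior) - M_target
        if abs(f) < tol:
            return mid
        if f > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def solve_omega_bar(
    Q_target: float, n_unsampled: int, prior: DegreePrior, tol: float = 1e-10
) -> float:
    """Tilt for the unsampled degrees: Q = (N - N-hat) E[q e^(-omega q)] / E[e^(-omega q)].

    Identical family to :func:`solve_omega` with kappa = 0 for every node.
    """
    return solve_omega(Q_target, np.zeros(n_unsampled, dtype=int), prior, tol=tol)


def _log_Ik(M: float, kappa, prior: DegreePrior, omega: float) -> float:
    """Saddle-point log of the constrained sampled-degree sum I^(k)(M)."""
    total = omega * M
    for kap, n in _kappa_groups(kappa).items():
        _, lw = _node_log_weights(prior, kap, omega)
        total += n * float(logsumexp(lw[np.isfinite(lw)]))
    return total


def _log_Ik_boundary(kappa, prior: DegreePrior, at: str) -> float:
    """Exact value of I^(k) when M sits at an end of its attainable range."""
    total = 0.0
    for kap, n in _kappa_groups(kappa).items():
        k_star = max(kap, prior.m_hat) if at == "lo" else prior.K
        with np.errstate(divide="ignore"):
            lw = (
                math.log(prior.pmf(np.array([k_star]))[0])
                + float(gammaln(k_star + 1.0) - gammaln(k_star - kap + 1.0))
            )
        total += n * lw
    return total


# ---------------------------------------------------------------------------
# size posterior
# ---------------------------------------------------------------------------


def _vectorized_tilt_means(prior: DegreePrior, omegas: np.ndarray) -> np.ndarray:
    """Mean of the omega-tilted degree prior for an array of tilts."""
    q = prior.support.astype(float)
    with np.errstate(divide="ignore"):
        logp = np.log(prior.probabilities)
    lw = logp[None, :] - np.outer(omegas, q)  # (n, s)
    lw -= lw.max(axis=1, keepdims=True)
    w = np.exp(lw)
    return (w * q).sum(axis=1) / w.sum(axis=1)


def _solve_omega_bar_vec(
    targets: np.ndarray, prior: DegreePrior, tol: float = 1e-11, max_iter: int = 200
) -> np.ndarray:
    """Vectorized bisection for the unsampled-degree tilt, one target mean per N."""
    n = len(targets)
    lo = np.full(n, -1.0)
    hi = np.full(n, 1.0)
    for _ in range(100):
        bad = _vectorized_tilt_means(prior, lo) <= targets
        if not bad.any():
            break
        lo[bad] *= 2.0
    for _ in range(100):
        bad = _vectorized_tilt_means(prior, hi) >= targets
        if not bad.any():
            break
        hi[bad] *= 2.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f = _vectorized_tilt_means(prior, mid) - targets
        hi = np.where(f < 0, mid, hi)
        lo = np.where(f >= 0, mid, lo)
        if np.max(np.abs(f)) < tol:
            break
    return 0.5 * (lo + hi)


def _log_Zq(prior: DegreePrior, omegas: np.ndarray) -> np.ndarray:
    q = prior.support.astype(float)
    with np.errstate(divide="ignore"):
        logp = np.log(prior.probabilities)
    lw = logp[None, :] - np.outer(omegas, q)
    m = lw.max(axis=1)
    return m + np.log(np.exp(lw - m[:, None]).sum(axis=1))


def _round_Q(Q_raw: float, parity: int) -> int | None:
    """Nearest integer to Q_raw with the required parity, within +-1."""
    base = int(round(Q_raw))
    for cand in (base, base - 1, base + 1):
        if cand % 2 == parity % 2 and abs(cand - Q_raw) <= 1.0:
            return cand
    return None


def size_posterior_degree(
    observed: ObservedSubgraph,
    model: DegreeEnsembleModel,
    M: int,
    N_grid: np.ndarray | None = None,
    boundary_tol: float = 0.01,
) -> PosteriorReport:
    """Posterior P(N | G-hat, M) over the size grid.

    For each N the hidden stub budget is Q = <k> N - 2 L-hat - M (rounded to
    the parity of M); the weight combines the prior pi(N), the matching
    combinatorics C_{M,N} = C(Q,M) M! matchings(Q-M) / matchings(2L), and
    the two tilted sums I^(k)(M) (N-independent) and I^(q)(M, N).
    Infeasible N (negative Q, Q < M, unattainable Q) receive zero mass.
    """
    if M < 0:
        raise ValueError("M must be >= 0")
    prior = model.degree_prior
    kappa = observed.kappa
    N_hat = observed.N_hat
    L_hat = observed.L_hat
    conv = model.double_factorial_convention
    if N_grid is None:
        N_grid = np.arange(max(model.N0 + 1, N_hat), model.size_prior.Nmax + 1)
    N_grid = np.asarray(N_grid, dtype=int)
    if len(N_grid) == 0:
        raise ValueError("empty N grid")

    # sampled-degree factor: independent of N
    lo_att, hi_att = _extra_range(_kappa_groups(kappa), prior)
    omega_star = None
    omega_residual = 0.0
    if lo_att == hi_att or M == lo_att:
        log_Ik = _log_Ik_boundary(kappa, prior, "lo") if M == lo_att else NEG_INF
    elif M == hi_att:
        log_Ik = _log_Ik_boundary(kappa, prior, "hi")
    elif lo_att < M < hi_att:
        omega_star = solve_omega(M, kappa, prior)
        omega_residual = abs(_M_of_omega(omega_star, _kappa_groups(kappa), prior) - M)
        log_Ik = _log_Ik(M, kappa, prior, omega_star)
    else:
        log_Ik = NEG_INF
    if log_Ik == NEG_INF:
        raise InfeasibleNodeError(
            f"M={M} incompatible with the observed degrees under the prior support"
        )

    q_min = int(prior.support[prior.probabilities > 0].min())
    q_max = int(prior.support[prior.probabilities > 0].max())

    log_w = np.full(len(N_grid), NEG_INF)
    Q_vals = np.full(len(N_grid), -1, dtype=int)
    interior = []
    targets = []
    log_pi = model.size_prior.log_pmf(N_grid)
    for idx, N in enumerate(N_grid):
        if not np.isfinite(log_pi[idx]):
            continue
        L = model.target_link_count(int(N))
        # Q = <k>N - 2L_hat - M rounded to the parity of M: with 2L = 2 round(<k>N/2)
        # the stub-conservation value 2L - 2L_hat - M is that rounding
        Q = 2 * L - 2 * L_hat - M
        if _round_Q(model.mean_degree * N - 2 * L_hat - M, M) is None:
            continue
        if Q < M or Q < 0:
            continue
        n_u = int(N) - N_hat
        if n_u == 0:
            if Q != 0:
                continue
            log_Iq = 0.0
        else:
            if not (n_u * q_min <= Q <= n_u * q_max):
                continue
            t = Q / n_u
            if Q == n_u * q_min:
                log_Iq = n_u * math.log(prior.pmf(np.array([q_min]))[0])
            elif Q == n_u * q_max:
                log_Iq = n_u * math.log(prior.pmf(np.array([q_max]))[0])
            else:
                interior.append(idx)
                targets.append(t)
                Q_vals[idx] = Q
                log_w[idx] = 0.0  # placeholder; filled after the vector solve
                continue
        Q_vals[idx] = Q
        log_C = (
            log_factorial(M)
            + log_double_factorial(Q - M, conv)
            + log_binom(Q, M)
            - log_double_factorial(2 * L, conv)
        )
        log_w[idx] = log_pi[idx] + log_C + log_Ik + log_Iq

    omega_bar_residual = 0.0
    if interior:
        interior = np.asarray(interior)
        targets = np.asarray(targets)
        omegas = _solve_omega_bar_vec(targets, prior)
        omega_bar_residual = float(
            np.max(np.abs(_vectorized_tilt_means(prior, omegas) - targets))
        )
        log_Zs = _log_Zq(prior, omegas)
        for pos, idx in enumerate(interior):
            N = int(N_grid[idx])
            Q = Q_vals[idx]
            n_u = N - N_hat
            L = model.target_link_count(N)
            log_C = (
                log_factorial(M)
                + log_double_factorial(Q - M, conv)
                + log_binom(Q, M)
                - log_double_factorial(2 * L, conv)
            )
            log_Iq = omegas[pos] * Q + n_u * log_Zs[pos]
            log_w[idx] = log_pi[idx] + log_C + log_Ik + log_Iq

    if not np.any(np.isfinite(log_w)):
        raise ValueError("all N in the grid are infeasible for this (G-hat, M)")
    probs = np.zeros(len(N_grid))
    finite = np.isfinite(log_w)
    probs[finite] = np.exp(log_w[finite] - logsumexp(log_w[finite]))
    flags = {
        "lower_boundary_mass": float(probs[0]) > boundary_tol,
        "upper_boundary_mass": float(probs[-1]) > boundary_tol,
    }
    diagnostics = {
        "M": int(M),
        "omega_star": omega_star,
        "omega_star_residual": omega_residual,
        "omega_bar_max_residual": omega_bar_residual,
        "attainable_M_range": (int(lo_att), int(hi_att)),
        "convention": conv,
    }
    return PosteriorReport(
        N_grid=N_grid,
        log_weights=log_w,
        probabilities=probs,
        diagnostics=diagnostics,
        boundary_flags=flags,
    )


def infer_degree_pipeline(
    observed: ObservedSubgraph,
    model: DegreeEnsembleModel,
    M: int,
    N_grid: np.ndarray | None = None,
) -> PosteriorReport:
    """Size posterior plus per-node true-degree posteriors at the solved tilt."""
    report = size_posterior_degree(observed, model, M, N_grid)
    omega = report.diagnostics.get("omega_star")
    omega = 0.0 if omega is None else omega
    report.node_posteriors = [
        degree_posterior(int(kap), omega, model.degree_prior) for kap in observed.kappa
    ]
    report.diagnostics["mode_N"] = report.mode
    return report


def scan_M(
    observed: ObservedSubgraph,
    model: DegreeEnsembleModel,
    M_values,
    N_grid: np.ndarray | None = None,
) -> dict[int, PosteriorReport]:
    """One report per conditioning value of M."""
    return {
        int(M): infer_degree_pipeline(observed, model, int(M), N_grid)
        for M in M_values
    }
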