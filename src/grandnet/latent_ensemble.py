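"""Grand-canonical ensemble of sparse networks with given latent-variable distribution.

Each node carries a nonnegative latent variable theta drawn i.i.d. from a
discrete prior p(theta); given the node count N, every unordered pair links
independently with

    p_N(theta_i, theta_j) = (theta_i theta_j / N) / (1 + theta_i theta_j / N),

which is bounded by 1 for all latent values, so no structural cutoff is
needed.  The joint law P(G, theta, N) = pi(N) prod_i p(theta_i) prod_{i<j}
Bernoulli(p_N) is exchangeable under simultaneous permutation of labels and
latent values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .network import NetworkState
from .priors import LatentPrior, SizePrior, sample_size

__all__ = [
    "LatentEnsembleModel",
    "LatentNetworkDraw",
    "link_prob",
    "generate",
    "hamiltonian_latent",
    "shannon_entropy_fixed",
    "entropy_decomposition_latent",
    "marginal_link_prob_latent",
    "conditional_link_prob_latent",
    "conditional_link_prob_latent_fixed_N",
]

# direct generation is O(N^2) pairs; refuse sizes where that is unreasonable
MAX_DIRECT_N = 10_000


@dataclass(frozen=True)
class LatentEnsembleModel:
    size_prior: SizePrior
    latent_prior: LatentPrior


@dataclass
class LatentNetworkDraw:
    """A network together with the latent values that generated it."""

    N: int
    theta: np.ndarray
    state: NetworkState


def link_prob(theta_i, theta_j, N):
    """p_N(theta_i, theta_j) = (t t'/N) / (1 + t t'/N), always <= 1."""
    x = np.asarray(theta_i, dtype=float) * np.asarray(theta_j, dtype=float) / N
    return x / (1.0 + x)


def generate(model: LatentEnsembleModel, rng: np.random.Generator, N: int | None = None) -> LatentNetworkDraw:
    """Direct sampler: N ~ pi(N), theta_i ~ p(theta) i.i.d., pairs ~ Bernoulli(p_N)."""
    if N is None:
        N = sample_size(model.size_prior, rng)
    if N > MAX_DIRECT_N:
        raise ValueError(f"direct generation capped at N={MAX_DIRECT_N} (got {N})")
    theta = model.latent_prior.sample(rng, size=N)
    iu, ju = np.triu_indices(N, k=1)
    p = link_prob(theta[iu], theta[ju], N)
    hit = rng.random(len(p)) < p
    state = NetworkState(N, zip(iu[hit].tolist(), ju[hit].tolist()))
    return LatentNetworkDraw(N=N, theta=theta, state=state)


def _log_prior_theta(model: LatentEnsembleModel, theta: np.ndarray) -> np.ndarray:
    grid = model.latent_prior.grid
    idx = np.searchsorted(grid, theta)
    idx = np.clip(idx, 0, len(grid) - 1)
    if not np.allclose(grid[idx], theta):
        raise ValueError("theta values must lie on the prior grid")
    with np.errstate(divide="ignore"):
        return np.log(model.latent_prior.probabilities[idx])


def hamiltonian_latent(draw: LatentNetworkDraw, model: LatentEnsembleModel) -> float:
    """H = -ln pi(N) - sum_i ln p(theta_i) - sum_{i<j} Bernoulli log-likelihood.

    exp(-H) reproduces the hierarchical product pi(N) prod p(theta_i)
    prod_{i<j} p_N^a (1-p_N)^(1-a).  An observed link between nodes whose
    kernel probability is exactly zero makes the configuration impossible;
    this is reported as +inf (math.inf), not an exception.
    """
    N = draw.N
    theta = np.asarray(draw.theta, dtype=float)
    if len(theta) != N or draw.state.N != N:
        raise ValueError("draw is inconsistent: |theta| and state.N must equal N")
    lp_N = float(model.size_prior.log_pmf(np.array([N]))[0])
    if not np.isfinite(lp_N):
        return math.inf
    lp_theta = _log_prior_theta(model, theta)
    if not np.all(np.isfinite(lp_theta)):
        return math.inf
    iu, ju = np.triu_indices(N, k=1)
    x = theta[iu] * theta[ju] / N
    # log p = log x - log1p(x); log(1-p) = -log1p(x)
    a = np.zeros(len(iu), dtype=bool)
    if draw.state.edges:
        # triu_indices enumerates pairs row-major; locate each edge arithmetically
        first = np.cumsum(np.concatenate(([0], np.arange(N - 1, 0, -1))))
        for i, j in draw.state.edges:
            a[first[i] + (j - i - 1)] = True
    log1px = np.log1p(x)
    with np.errstate(divide="ignore"):
        log_x = np.log(x)
    ll_links = log_x[a] - log1px[a]
    if np.any(~np.isfinite(ll_links)):
        return math.inf  # impossible configuration: a_ij = 1 with p_N = 0
    ll = float(ll_links.sum() - log1px[~a].sum())
    return float(-lp_N - lp_theta.sum() - ll)


def shannon_entropy_fixed(theta, N: int) -> float:
    """Pairwise Bernoulli entropy S_N(theta) of the conditional graph law."""
    theta = np.asarray(theta, dtype=float)
    if len(theta) != N:
        raise ValueError("need one theta per node")
    iu, ju = np.triu_indices(N, k=1)
    p = link_prob(theta[iu], theta[ju], N)
    return float(_bernoulli_entropy(p).sum())


def _bernoulli_entropy(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    mask = (p > 0) & (p < 1)
    pm = p[mask]
    out[mask] = -(pm * np.log(pm) + (1 - pm) * np.log1p(-pm))
    return out


@dataclass(frozen=True)
class LatentEntropyDecomposition:
    S_size: float
    S_latent: float
    S_graphs: float
    mc_standard_error: float = 0.0

    @property
    def total(self) -> float:
        return self.S_size + self.S_latent + self.S_graphs


def entropy_decomposition_latent(
    model: LatentEnsembleModel,
    n_mc: int = 1000,
    rng: np.random.Generator | None = None,
    method: str = "mc",
) -> LatentEntropyDecomposition:
    """S = S_pi + <S_p(theta)>_pi + <S_N(theta)>_{pi, p(theta)}.

    The first two terms are closed forms (the latent variables are i.i.d.,
    so the sequence entropy is exactly N * H[p(theta)] averaged over pi).
    The third is a Monte Carlo average of the pairwise Bernoulli entropy
    over theta draws, or an exact enumeration over the theta grid with
    ``method="enumerate"`` (small N and grids only).
    """
    if rng is None:
        rng = np.random.default_rng()
    sp = model.size_prior
    S_size = sp.entropy()
    S_latent = float(np.sum(sp.weights * sp.support) * model.latent_prior.entropy())
    if method == "enumerate":
        from itertools import product

        S_graphs = 0.0
        grid = model.latent_prior.grid
        probs = model.latent_prior.probabilities
        for N, w in zip(sp.support, sp.weights):
            if w <= 0:
                continue
            if len(grid) ** int(N) > 2_000_000:
                raise ValueError("enumeration too large; use method='mc'")
            for combo in product(range(len(grid)), repeat=int(N)):
                p_theta = math.prod(probs[c] for c in combo)
                if p_theta <= 0:
                    continue
                theta = grid[list(combo)]
                S_graphs += w * p_theta * shannon_entropy_fixed(theta, int(N))
        return LatentEntropyDecomposition(S_size, S_latent, S_graphs, 0.0)
    if method != "mc":
        raise ValueError(f"unknown method {method!r}")
    vals = np.empty(n_mc)
    for t in range(n_mc):
        N = sample_size(sp, rng)
        theta = model.latent_prior.sample(rng, size=N)
        vals[t] = shannon_entropy_fixed(theta, N)
    return LatentEntropyDecomposition(
        S_size,
        S_latent,
        float(vals.mean()),
        float(vals.std(ddof=1) / math.sqrt(n_mc)) if n_mc > 1 else math.inf,
    )


# ---------------------------------------------------------------------------
# link marginals
# ---------------------------------------------------------------------------


def marginal_link_prob_latent(model: LatentEnsembleModel) -> float:
    """p_ij = sum_N pi(N) sum_{theta,theta'} p(theta) p(theta') p_N(theta,theta')."""
    sp = model.size_prior
    grid = model.latent_prior.grid
    probs = model.latent_prior.probabilities
    tt = np.outer(grid, grid)
    pp = np.outer(probs, probs)
    total = 0.0
    for N, w in zip(sp.support, sp.weights):
        if w <= 0:
            continue
        x = tt / N
        total += w * float(np.sum(pp * x / (1.0 + x)))
    return total


def conditional_link_prob_latent(model: LatentEnsembleModel, theta: float, theta_prime: float) -> float:
    """p(theta, theta') = theta theta' sum_N pi(N) / (N + theta theta').

    This equals the exact pair marginal sum_N pi(N) p_N(theta, theta').
    """
    sp = model.size_prior
    tt = theta * theta_prime
    return float(tt * np.sum(sp.weights / (sp.support + tt)))


def conditional_link_prob_latent_fixed_N(theta: float, theta_prime: float, N: int) -> float:
    """p_N(theta, theta'): the Bernoulli kernel itself."""
    return float(link_prob(theta, theta_prime, N))
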