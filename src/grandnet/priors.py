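"""Hierarchical priors: network-size prior pi(N), degree prior p(k), latent prior p(theta).

The size prior is defined on integers N in [N0, Nmax].  The model itself
places no upper bound on N, so every numeric sum over N (entropies,
marginals, posteriors) is truncated at Nmax; for families with an
analytically known tail (exponential) Nmax can be chosen automatically so
that the discarded tail mass is below a tolerance, while heavy-tailed
families (power law) require an explicit, reported truncation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp


class PriorError(ValueError):
    """Invalid prior specification."""


# ---------------------------------------------------------------------------
# size prior pi(N)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SizePrior:
    """Normalized prior over the total number of nodes N on [N0, Nmax]."""

    family: str
    params: dict
    N0: int
    Nmax: int
    log_weights: np.ndarray = field(repr=False)

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.N0, self.Nmax + 1)

    @property
    def weights(self) -> np.ndarray:
        return np.exp(self.log_weights)

    def log_pmf(self, N) -> np.ndarray:
        """Normalized log pi(N); -inf outside [N0, Nmax]."""
        N = np.asarray(N)
        out = np.full(N.shape, -np.inf, dtype=float)
        ok = (N >= self.N0) & (N <= self.Nmax)
        out[ok] = self.log_weights[N[ok].astype(int) - self.N0]
        return out if out.shape else float(out)

    def quantile(self, p: float) -> int:
        cdf = np.cumsum(self.weights)
        return int(self.support[np.searchsorted(cdf, p)])

    def entropy(self) -> float:
        w = self.weights
        nz = w > 0
        return float(-np.sum(w[nz] * self.log_weights[nz]))


def _unnormalized_log_weights(family: str, params: dict, N: np.ndarray) -> np.ndarray:
    if family == "exponential":
        mu = float(params["mu"])
        if mu <= 0:
            raise PriorError("exponential size prior requires mu > 0")
        return -mu * N.astype(float)
    if family == "power_law":
        nu = float(params["nu"])
        if nu <= 1:
            raise PriorError("power-law size prior requires nu > 1: normalization diverges")
        return -nu * np.log(N.astype(float))
    if family == "delta":
        Nbar = int(params["Nbar"])
        lw = np.full(N.shape, -np.inf)
        lw[N == Nbar] = 0.0
        if not np.any(N == Nbar):
            raise PriorError(f"delta size prior at {Nbar} outside [N0, Nmax]")
        return lw
    if family == "uniform":
        return np.zeros(N.shape)
    if family == "table":
        probs = np.asarray(params["probs"], dtype=float)
        if probs.shape != N.shape:
            raise PriorError("table size prior needs one probability per N in [N0, Nmax]")
        if np.any(probs < 0) or probs.sum() <= 0:
            raise PriorError("table probabilities must be nonnegative with positive sum")
        with np.errstate(divide="ignore"):
            return np.log(probs)
    raise PriorError(f"unknown size-prior family {family!r}")


def build_size_prior(
    family: str,
    params: dict | None = None,
    *,
    N0: int = 1,
    Nmax: int | None = None,
    tail_eps: float = 1e-10,
) -> SizePrior:
    """Build a normalized size prior on [N0, Nmax].

    For the exponential family Nmax may be omitted: it is then chosen as the
    smallest bound for which the untruncated tail mass beyond Nmax is below
    ``tail_eps``.  The delta family pins Nmax to the atom.  The power-law
    family has no automatic bound (heavy tail) and requires Nmax.
    """
    params = dict(params or {})
    if N0 < 1:
        raise PriorError("N0 must be >= 1")
    if family == "delta" and Nmax is None:
        Nmax = int(params["Nbar"])
    if family == "exponential" and Nmax is None:
        mu = float(params.get("mu", 0.0))
        if mu <= 0:
            raise PriorError("exponential size prior requires mu > 0")
        # tail mass of the geometric tail beyond Nmax relative to mass at N0
        Nmax = N0 + int(np.ceil(-np.log(tail_eps) / mu)) + 1
    if Nmax is None:
        raise PriorError(f"family {family!r} requires an explicit Nmax")
    Nmax = int(Nmax)
    if Nmax < N0:
        raise PriorError(f"invalid range: Nmax={Nmax} < N0={N0}")
    N = np.arange(N0, Nmax + 1)
    lw = _unnormalized_log_weights(family, params, N)
    lw = lw - logsumexp(lw)
    return SizePrior(family=family, params=params, N0=N0, Nmax=Nmax, log_weights=lw)


def sample_size(prior: SizePrior, rng: np.random.Generator, size: int | None = None):
    """Draw N from pi(N)."""
    draws = rng.choice(prior.support, size=size, p=prior.weights)
    return int(draws) if size is None else draws.astype(int)


# ---------------------------------------------------------------------------
# degree prior p(k)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DegreePrior:
    """Degree distribution truncated to [m_hat, K] and renormalized."""

    support: np.ndarray
    probabilities: np.ndarray
    m_hat: int
    K: int

    @property
    def mean_degree(self) -> float:
        return float(np.sum(self.support * self.probabilities))

    def pmf(self, k) -> np.ndarray:
        k = np.asarray(k)
        out = np.zeros(k.shape, dtype=float)
        ok = (k >= self.m_hat) & (k <= self.K)
        out[ok] = self.probabilities[k[ok].astype(int) - self.m_hat]
        return out if out.shape else float(out)

    def log_pmf(self, k) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.pmf(k))

    def entropy(self) -> float:
        p = self.probabilities
        nz = p > 0
        return float(-np.sum(p[nz] * np.log(p[nz])))

    def sample(self, rng: np.random.Generator, size=None):
        draws = rng.choice(self.support, size=size, p=self.probabilities)
        return int(draws) if size is None else draws.astype(int)


def build_degree_prior(raw_probabilities, m_hat: int = 0, K: int | None = None) -> DegreePrior:
    """Truncate raw degree weights to [m_hat, K] and renormalize.

    ``raw_probabilities`` is indexed by degree starting at 0 (entries outside
    [m_hat, K] are zeroed by the hard minimum/maximum degree bounds before
    renormalization).
    """
    raw = np.asarray(raw_probabilities, dtype=float)
    if np.any(raw < 0):
        raise PriorError("degree weights must be nonnegative")
    if K is None:
        K = len(raw) - 1
    if m_hat < 0 or K < m_hat:
        raise PriorError(f"need 0 <= m_hat <= K, got m_hat={m_hat}, K={K}")
    full = np.zeros(K + 1)
    full[: min(len(raw), K + 1)] = raw[: K + 1]
    trunc = full[m_hat : K + 1]
    total = trunc.sum()
    if total <= 0:
        raise PriorError(f"degree prior has zero mass on [{m_hat}, {K}]: empty support")
    return DegreePrior(
        support=np.arange(m_hat, K + 1),
        probabilities=trunc / total,
        m_hat=m_hat,
        K=K,
    )


def exponential_degree_prior(m: float, m_hat: int = 0, K: int = 16) -> DegreePrior:
    """p(k) proportional to exp(-k/m) on [m_hat, K]."""
    k = np.arange(K + 1)
    return build_degree_prior(np.exp(-k / m), m_hat, K)


def power_law_degree_prior(gamma: float, shift: float = 3.0, m_hat: int = 0, K: int = 16) -> DegreePrior:
    """p(k) proportional to (shift + k)^(-gamma) on [m_hat, K]."""
    k = np.arange(K + 1)
    return build_degree_prior((shift + k) ** (-gamma), m_hat, K)


# ---------------------------------------------------------------------------
# latent prior p(theta)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LatentPrior:
    """Discrete prior for the per-node latent variables theta >= 0."""

    grid: np.ndarray
    probabilities: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.sum(self.grid * self.probabilities))

    def entropy(self) -> float:
        p = self.probabilities
        nz = p > 0
        return float(-np.sum(p[nz] * np.log(p[nz])))

    def sample(self, rng: np.random.Generator, size=None):
        draws = rng.choice(self.grid, size=size, p=self.probabilities)
        return float(draws) if size is None else draws


def build_latent_prior(grid, raw_probabilities) -> LatentPrior:
    """Normalize a discrete latent-variable prior on a nonnegative grid."""
    grid = np.asarray(grid, dtype=float)
    raw = np.asarray(raw_probabilities, dtype=float)
    if grid.shape != raw.shape:
        raise PriorError("grid and probabilities must have the same length")
    if np.any(grid < 0):
        raise PriorError("latent grid values must be >= 0")
    if np.any(raw < 0) or raw.sum() <= 0:
        raise PriorError("latent weights must be nonnegative with positive sum")
    if len(np.unique(grid)) != len(grid):
        raise PriorError("latent grid values must be distinct")
    return LatentPrior(grid=grid, probabilities=raw / raw.sum())


def exponential_latent_prior(m: float, theta_max: float = 30.0, step: float = 0.25) -> LatentPrior:
    """Discretized p(theta) proportional to exp(-theta/m) on {0, step, ..., theta_max}."""
    grid = np.arange(0.0, theta_max + step / 2, step)
    return build_latent_prior(grid, np.exp(-grid / m))
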