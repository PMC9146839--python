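"""Log-domain combinatorial primitives shared across the ensembles.

All quantities are returned as natural logarithms so that stub-matching
counts for networks with thousands of links never overflow.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

__all__ = [
    "log_factorial",
    "log_binom",
    "log_double_factorial",
    "log_matchings",
]


def log_factorial(n):
    """ln n! for integer n >= 0 (vectorized)."""
    n = np.asarray(n, dtype=float)
    if np.any(n < 0):
        raise ValueError("factorial requires n >= 0")
    return gammaln(n + 1.0)


def log_binom(n: int, k: int) -> float:
    """ln C(n, k); 0 <= k <= n required."""
    if k < 0 or k > n:
        raise ValueError(f"binomial coefficient requires 0 <= k <= n, got ({n}, {k})")
    return float(gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0))


def log_double_factorial(x: int, convention: str = "matching") -> float:
    """Logarithm of the double-factorial-type count of stub pairings.

    convention="matching" returns ln of the number of perfect matchings of
    ``x`` labelled objects, i.e. ln (x-1)!! for even x (and 0 for x = 0);
    odd x has no perfect matching and raises.  convention="literal" returns
    ln x!! with the standard recursion x!! = x (x-2)!!, 0!! = (-1)!! = 1.

    The matching convention is the one under which configuration-model
    counting identities (Bender-Canfield and the constrained subgraph
    counts) are exact; the literal convention is kept for sensitivity
    checks.  At fixed link count the term is an additive constant of the
    Hamiltonian and cancels from all fixed-size acceptance ratios.
    """
    if x < 0 or x != int(x):
        raise ValueError(f"x must be a nonnegative integer, got {x!r}")
    x = int(x)
    if convention == "matching":
        if x % 2 != 0:
            raise ValueError(
                f"no perfect matching of an odd number of objects (x={x})"
            )
        m = x // 2
        # (x-1)!! = x! / (2^m m!)
        return float(gammaln(x + 1.0) - m * np.log(2.0) - gammaln(m + 1.0))
    if convention == "literal":
        if x % 2 == 0:
            m = x // 2
            return float(m * np.log(2.0) + gammaln(m + 1.0))
        m = (x - 1) // 2
        return float(gammaln(x + 1.0) - m * np.log(2.0) - gammaln(m + 1.0))
    raise ValueError(f"unknown double-factorial convention {convention!r}")


def log_matchings(n_stubs: int) -> float:
    """ln of the number of perfect matchings of ``n_stubs`` labelled stubs."""
    return log_double_factorial(n_stubs, "matching")
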