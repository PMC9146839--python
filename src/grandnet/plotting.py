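"""Minimal figures: size posteriors vs prior, chain traces, degree histograms."""

from __future__ import annotations

import numpy as np

from .reports import PosteriorReport


def plot_size_posterior(report: PosteriorReport, size_prior=None, ax=None, label=None):
    """Posterior P(N | data) with the prior dashed for comparison."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(report.N_grid, report.probabilities, label=label or "posterior")
    if size_prior is not None:
        prior = np.exp(size_prior.log_pmf(report.N_grid))
        prior /= prior.sum()
        ax.plot(report.N_grid, prior, "--", color="gray", label="prior")
    ax.set_xlabel("N")
    ax.set_ylabel("P(N)")
    ax.legend()
    return ax


def plot_chain_trace(result, ax=None):
    """N(t) trace of a grand-canonical Metropolis run."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    steps = (np.arange(len(result.N_trace)) + 1) * result.record_every
    ax.plot(steps, result.N_trace, lw=0.5)
    ax.set_xlabel("step")
    ax.set_ylabel("N(t)")
    return ax


def plot_degree_histogram(result, target_pmf=None, ax=None):
    """Post-burn-in degree histogram with the target p(k) overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    k = np.arange(len(result.degree_histogram))
    ax.plot(k, result.degree_histogram, "o", label="chain")
    if target_pmf is not None:
        ax.plot(k, target_pmf, "-", label="target p(k)")
    ax.set_xlabel("k")
    ax.set_ylabel("p(k)")
    ax.set_yscale("log")
    ax.legend()
    return ax
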