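import numpy as np
import pytest

from grandnet import (
    DegreeEnsembleModel,
    LatentEnsembleModel,
    build_degree_prior,
    build_latent_prior,
    build_size_prior,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def tiny_degree_model():
    """Enumerable degree ensemble: N in {4, 6}, degrees in {1, 2}."""
    size_prior = build_size_prior("table", {"probs": [0.6, 0.0, 0.4]}, N0=4, Nmax=6)
    degree_prior = build_degree_prior([0.0, 0.5, 0.5], m_hat=1, K=2)
    return DegreeEnsembleModel(size_prior=size_prior, degree_prior=degree_prior)


@pytest.fixture
def tiny_latent_model():
    """Enumerable latent ensemble: N in {3, 4}, theta in {0.5, 2.0}."""
    size_prior = build_size_prior("table", {"probs": [0.5, 0.5]}, N0=3, Nmax=4)
    latent_prior = build_latent_prior([0.5, 2.0], [0.7, 0.3])
    return LatentEnsembleModel(size_prior=size_prior, latent_prior=latent_prior)


@pytest.fixture
def fig_degree_model():
    """Scaled version of the exponential-degree study conditions."""
    from grandnet.priors import exponential_degree_prior

    size_prior = build_size_prior("exponential", {"mu": 1 / 200}, N0=100)
    return DegreeEnsembleModel(
        size_prior=size_prior,
        degree_prior=exponential_degree_prior(5.0, 0, 16),
    )
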