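"""Bayesian estimation of each molecule's mean STR and the 2-of-3
similarity rule for adjacent cascade steps.

Model: replicate STR values y_i ~ Normal(mu, s) with weakly informative
priors mu ~ Normal(0, prior_mu_sd^2) and s ~ HalfNormal(prior_sigma_scale).
This is the simplest model under which the expected a posteriori (EAP) value
of mu plays the role of the classical mean. Sampling uses independent
affine-invariant ensemble (stretch-move) MCMC chains; convergence is
monitored with the split-chain Gelman-Rubin statistic (converged when
R_hat <= 1.1).

Two STRs are "similar" when at least two of three criteria hold, each
evaluated after rounding to one decimal (the reporting precision of the
statistics):

1. effect size |delta| = |EAP_A - EAP_B| / s_A <= 0.3 (Cohen-small), where
   s_A is the posterior mean of A's replicate-level standard deviation —
   Cohen's convention scales mean differences by the population spread;
2. probability of dominance pi_d in [0.4, 0.6], where pi_d is the
   posterior-predictive probability that a new observation from A exceeds
   one from B;
3. direction probability d_pi in [0.4, 0.6], where d_pi is the larger of the
   posterior probabilities that mu_A > mu_B and mu_B > mu_A (so d_pi >= 0.5;
   values near 0.5 indicate indistinguishable means).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import emcee
import numpy as np

with warnings.catch_warnings():
    warnings.simplefilter("ignore", FutureWarning)
    import arviz as az


class InsufficientReplicatesError(ValueError):
    """Raised when fewer than five replicate values are available."""


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings. ``n_draws`` is the number of retained posterior
    draws per chain; ``n_warmup`` the number of discarded ensemble steps."""

    n_chains: int = 4
    n_draws: int = 2000
    n_warmup: int = 1000
    n_walkers: int = 8
    seed: int = 0
    prior_mu_sd: float = 10.0
    prior_sigma_scale: float = 5.0

    def __post_init__(self):
        if self.n_chains < 2:
            raise ValueError("R_hat needs at least 2 chains")
        if self.n_draws <= 0 or self.n_warmup < 0:
            raise ValueError("need n_draws > 0 and n_warmup >= 0")
        if self.n_walkers < 4:
            raise ValueError("the stretch move needs at least 4 walkers for 2 parameters")


@dataclass
class PosteriorSummary:
    """Posterior of one molecule's mean STR.

    ``eap_mu`` is the posterior mean of mu (EAP), ``post_sd`` its posterior
    standard deviation; ``mu_draws``/``sigma_draws`` have shape
    (n_chains, n_draws). ``converged`` is False when R_hat > 1.1 — the result
    is still returned but flagged.
    """

    molecule_id: str
    eap_mu: float
    post_sd: float
    r_hat: float
    mu_draws: np.ndarray
    sigma_draws: np.ndarray
    n_used: int

    @property
    def converged(self) -> bool:
        return self.r_hat <= 1.1

    def flat(self, which: str = "mu") -> np.ndarray:
        arr = self.mu_draws if which == "mu" else self.sigma_draws
        return np.asarray(arr).reshape(-1)


@dataclass(frozen=True)
class SimilarityThresholds:
    effect_size_max: float = 0.3
    band_low: float = 0.4
    band_high: float = 0.6
    round_decimals: int = 1


@dataclass(frozen=True)
class SimilarityAssessment:
    """Pairwise verdict for one cascade edge."""

    pair: tuple[str, str]
    d_mu: float
    effect_size: float
    pi_d: float
    d_pi: float
    c1: bool
    c2: bool
    c3: bool
    similar: bool


def trim_outliers(replicates, min_keep: int = 5) -> np.ndarray:
    """Boxplot-rule outlier exclusion with a floor of ``min_keep`` values.

    Values outside median +/- 1.5*IQR are removed, most extreme first; if
    removal would leave fewer than ``min_keep`` values, the least extreme
    removed values are readmitted until the floor holds. The quartiles are
    Tukey's hinges (medians of the lower/upper half), the convention of the
    original boxplot rule; interpolated quartiles over-flag at these sample
    sizes.
    """
    x = np.asarray(replicates, dtype=float)
    if len(x) < min_keep:
        raise InsufficientReplicatesError(
            f"need at least {min_keep} replicates, got {len(x)}"
        )
    med = np.median(x)
    xs = np.sort(x)
    half = (len(xs) + 1) // 2
    q1 = float(np.median(xs[:half]))
    q3 = float(np.median(xs[len(xs) - half:]))
    iqr = q3 - q1
    lo, hi = med - 1.5 * iqr, med + 1.5 * iqr
    is_out = (x < lo) | (x > hi)
    if not is_out.any():
        return x.copy()
    # removal order: most extreme (largest distance from median) first
    order = np.argsort(-np.abs(x - med), kind="stable")
    removal = [i for i in order if is_out[i]]
    n_remove = min(len(removal), len(x) - min_keep)
    removed = set(removal[:n_remove])
    return np.array([v for i, v in enumerate(x) if i not in removed])


def _log_prob_factory(y: np.ndarray, cfg: McmcConfig):
    """Vectorized log posterior over theta = (mu, s)."""
    n = len(y)

    def log_prob(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        mu, s = theta[:, 0], theta[:, 1]
        bad = s <= 0
        s_safe = np.where(bad, 1.0, s)
        resid = (y[None, :] - mu[:, None]) / s_safe[:, None]
        loglik = -0.5 * np.sum(resid**2, axis=1) - n * np.log(s_safe)
        logprior = (
            -0.5 * (mu / cfg.prior_mu_sd) ** 2
            - 0.5 * (s_safe / cfg.prior_sigma_scale) ** 2
        )
        return np.where(bad, -np.inf, loglik + logprior)

    return log_prob


def fit_posterior(replicates, cfg: McmcConfig | None = None,
                  molecule_id: str = "") -> PosteriorSummary:
    """Fit the Normal replicate model by ensemble MCMC.

    Runs ``cfg.n_chains`` independent stretch-move ensembles seeded from
    ``cfg.seed``; bit-reproducible for a fixed config.
    """
    cfg = cfg or McmcConfig()
    y = np.asarray(replicates, dtype=float)
    if len(y) < 5:
        raise InsufficientReplicatesError(
            f"need at least 5 replicates after trimming, got {len(y)}"
        )
    if np.ptp(y) == 0:
        # All replicates identical (e.g. molecules with no detectable signal,
        # whose STR is 0 in every replicate): the likelihood diverges as
        # s -> 0, the posterior collapses to a point mass and MCMC is
        # undefined. Return the collapsed posterior analytically.
        shape = (cfg.n_chains, cfg.n_draws)
        return PosteriorSummary(
            molecule_id=molecule_id,
            eap_mu=float(y[0]),
            post_sd=0.0,
            r_hat=1.0,
            mu_draws=np.full(shape, float(y[0])),
            sigma_draws=np.zeros(shape),
            n_used=len(y),
        )
    log_prob = _log_prob_factory(y, cfg)
    y_mean, y_sd = float(y.mean()), float(y.std(ddof=1))
    scale = y_sd if y_sd > 0 else max(abs(y_mean) * 1e-3, 1e-8)

    steps_keep = int(np.ceil(cfg.n_draws / cfg.n_walkers))
    seeds = np.random.SeedSequence(cfg.seed).generate_state(cfg.n_chains)
    mu_chains, sigma_chains = [], []
    for c in range(cfg.n_chains):
        rs = np.random.RandomState(int(seeds[c]))
        p0 = np.column_stack(
            [
                y_mean + scale * rs.randn(cfg.n_walkers),
                np.abs(scale * (1.0 + 0.5 * rs.randn(cfg.n_walkers))) + 1e-12,
            ]
        )
        sampler = emcee.EnsembleSampler(cfg.n_walkers, 2, log_prob, vectorize=True)
        sampler.random_state = np.random.RandomState(int(seeds[c])).get_state()
        sampler.run_mcmc(p0, cfg.n_warmup + steps_keep, progress=False)
        chain = sampler.get_chain(discard=cfg.n_warmup)  # (steps, walkers, 2)
        flat = chain.reshape(-1, 2)[: cfg.n_draws]
        mu_chains.append(flat[:, 0])
        sigma_chains.append(flat[:, 1])
    mu = np.asarray(mu_chains)       # (chains, draws)
    sigma = np.asarray(sigma_chains)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r_hat = float(az.rhat(az.convert_to_dataset(mu))["x"].values)
    summary = PosteriorSummary(
        molecule_id=molecule_id,
        eap_mu=float(mu.mean()),
        post_sd=float(mu.std(ddof=1)),
        r_hat=r_hat,
        mu_draws=mu,
        sigma_draws=sigma,
        n_used=len(y),
    )
    if not summary.converged:
        warnings.warn(
            f"MCMC for {molecule_id or 'molecule'} did not converge "
            f"(R_hat = {r_hat:.3f} > 1.1)",
            RuntimeWarning,
            stacklevel=2,
        )
    return summary


def _aligned(a: PosteriorSummary, b: PosteriorSummary):
    xa, xb = a.flat("mu"), b.flat("mu")
    sa, sb = a.flat("sigma"), b.flat("sigma")
    n = min(len(xa), len(xb))
    return xa[:n], sa[:n], xb[:n], sb[:n]


def effect_size(a: PosteriorSummary, b: PosteriorSummary,
                denominator: str = "first") -> float:
    """Cohen-style effect size: |EAP_A - EAP_B| divided by the posterior
    mean of the replicate-level standard deviation s of the first (upstream)
    molecule (``denominator="pooled"`` uses the RMS of both molecules' s
    instead). The denominator is the population spread, not the standard
    error of the mean. Asymmetric in (A, B) under the default."""
    sd_a = float(a.flat("sigma").mean())
    if denominator == "first":
        sd = sd_a
    elif denominator == "pooled":
        sd_b = float(b.flat("sigma").mean())
        sd = float(np.sqrt(0.5 * (sd_a**2 + sd_b**2)))
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    d = abs(a.eap_mu - b.eap_mu)
    if sd == 0:
        # collapsed posterior: identical means are a perfect match, any
        # difference is infinitely many spreads wide
        return 0.0 if d == 0 else float("inf")
    return d / sd


def prob_dominance(a: PosteriorSummary, b: PosteriorSummary,
                   rng: np.random.Generator | int | None = 0) -> float:
    """Posterior-predictive probability that a new STR observation from A
    exceeds one from B: per retained draw k, simulate
    y_A ~ Normal(mu_A^(k), s_A^(k)) and y_B likewise, and count y_A > y_B
    (ties, which only occur for collapsed posteriors, count one half).
    Satisfies pi_d(A,B) + pi_d(B,A) = 1 up to Monte-Carlo error."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    mu_a, s_a, mu_b, s_b = _aligned(a, b)
    ya = rng.normal(mu_a, s_a)
    yb = rng.normal(mu_b, s_b)
    return float(np.mean(ya > yb) + 0.5 * np.mean(ya == yb))


def prob_direction(a: PosteriorSummary, b: PosteriorSummary) -> float:
    """d_pi = max(P(mu_A > mu_B), P(mu_B > mu_A)) from paired posterior
    draws (ties count one half); always in [0.5, 1] and symmetric in
    (A, B)."""
    mu_a, _, mu_b, _ = _aligned(a, b)
    # compute both directions from counts so the result is exactly
    # symmetric in (A, B) despite floating-point rounding
    half_ties = 0.5 * np.mean(mu_a == mu_b)
    p = float(np.mean(mu_a > mu_b) + half_ties)
    q = float(np.mean(mu_b > mu_a) + half_ties)
    return max(p, q)


def similarity_verdict(
    pair: tuple[str, str],
    d_mu: float,
    effect: float,
    pi_d: float,
    d_pi: float,
    thresholds: SimilarityThresholds | None = None,
) -> SimilarityAssessment:
    """Apply the 2-of-3 rule to precomputed statistics.

    All statistics are rounded to ``thresholds.round_decimals`` before the
    inclusive comparisons, matching the precision at which such statistics
    are reported.
    """
    th = thresholds or SimilarityThresholds()
    r = lambda v: round(v, th.round_decimals)
    c1 = r(effect) <= th.effect_size_max
    c2 = th.band_low <= r(pi_d) <= th.band_high
    c3 = th.band_low <= r(d_pi) <= th.band_high
    return SimilarityAssessment(
        pair=tuple(pair),
        d_mu=d_mu,
        effect_size=effect,
        pi_d=pi_d,
        d_pi=d_pi,
        c1=bool(c1),
        c2=bool(c2),
        c3=bool(c3),
        similar=bool(c1 + c2 + c3 >= 2),
    )


def assess_pair(
    a: PosteriorSummary,
    b: PosteriorSummary,
    thresholds: SimilarityThresholds | None = None,
    rng: np.random.Generator | int | None = 0,
) -> SimilarityAssessment:
    """Full pairwise assessment of two fitted posteriors."""
    return similarity_verdict(
        pair=(a.molecule_id, b.molecule_id),
        d_mu=abs(a.eap_mu - b.eap_mu),
        effect=effect_size(a, b),
        pi_d=prob_dominance(a, b, rng=rng),
        d_pi=prob_direction(a, b),
        thresholds=thresholds,
    )
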