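"""Outlier trimming, posterior fitting and the 2-of-3 similarity rule."""

import numpy as np
import pytest
from scipy.stats import norm

from sigstr import (
    McmcConfig,
    assess_pair,
    effect_size,
    fit_posterior,
    prob_direction,
    prob_dominance,
    similarity_verdict,
    trim_outliers,
)
from sigstr.bayes import InsufficientReplicatesError

from conftest import LIGHT_MCMC, make_summary


class TestTrimOutliers:
    def test_removes_clear_outlier(self):
        kept = trim_outliers([2.0, 2.1, 1.9, 2.05, 1.95, 9.0])
        assert 9.0 not in kept
        assert len(kept) == 5
        assert sorted(kept) == [1.9, 1.95, 2.0, 2.05, 2.1]

    def test_clean_data_untouched(self):
        x = [0.08, 0.081, 0.079, 0.082, 0.078, 0.080]
        assert list(trim_outliers(x)) == x

    def test_floor_of_five_readmits(self):
        # both extremes flagged, but only one removal is allowed at n = 6
        kept = trim_outliers([2.0, 2.01, 1.99, 2.0, -5.0, 9.5])
        assert len(kept) == 5
        # the most extreme value goes first
        assert 9.5 not in kept and -5.0 in kept

    def test_five_values_never_trimmed(self):
        kept = trim_outliers([1.0, 2.0, 3.0, 4.0, 100.0])
        assert len(kept) == 5

    def test_too_few_raises(self):
        with pytest.raises(InsufficientReplicatesError):
            trim_outliers([1.0, 2.0, 3.0, 4.0])


class TestFitPosterior:
    def test_recovers_mean(self, rng):
        y = rng.normal(0.08, 0.01, size=6)
        post = fit_posterior(y, LIGHT_MCMC, molecule_id="m")
        assert post.eap_mu == pytest.approx(y.mean(), abs=4 * y.std() / np.sqrt(6))
        assert post.converged
        assert post.n_used == 6
        assert post.mu_draws.shape == (LIGHT_MCMC.n_chains, LIGHT_MCMC.n_draws)

    def test_bit_reproducible(self):
        y = [0.07, 0.09, 0.085, 0.075, 0.08, 0.082]
        a = fit_posterior(y, LIGHT_MCMC)
        b = fit_posterior(y, LIGHT_MCMC)
        assert np.array_equal(a.mu_draws, b.mu_draws)
        assert np.array_equal(a.sigma_draws, b.sigma_draws)
        assert a.eap_mu == b.eap_mu and a.r_hat == b.r_hat

    def test_seed_changes_draws(self):
        y = [0.07, 0.09, 0.085, 0.075, 0.08, 0.082]
        a = fit_posterior(y, LIGHT_MCMC)
        b = fit_posterior(y, McmcConfig(n_chains=2, n_draws=800,
                                        n_warmup=300, seed=1))
        assert not np.array_equal(a.mu_draws, b.mu_draws)

    def test_collapsed_posterior_for_identical_replicates(self):
        post = fit_posterior([0.0] * 6, LIGHT_MCMC, molecule_id="flat")
        assert post.eap_mu == 0.0
        assert post.post_sd == 0.0
        assert post.r_hat == 1.0
        assert np.all(post.sigma_draws == 0.0)

    def test_insufficient_replicates(self):
        with pytest.raises(InsufficientReplicatesError):
            fit_posterior([1.0, 2.0, 3.0], LIGHT_MCMC)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            McmcConfig(n_chains=1)
        with pytest.raises(ValueError):
            McmcConfig(n_walkers=2)
        with pytest.raises(ValueError):
            McmcConfig(n_draws=0)


class TestEffectSize:
    def test_first_molecule_denominator_oracle(self):
        a = make_summary("A", eap_mu=2.0, mu_sd=0.0, sigma_mean=1.0)
        b = make_summary("B", eap_mu=2.3, mu_sd=0.0, sigma_mean=5.0)
        assert effect_size(a, b) == pytest.approx(0.3)
        # asymmetric under the default: B's spread is 5
        assert effect_size(b, a) == pytest.approx(0.06)

    def test_pooled_denominator(self):
        a = make_summary("A", 2.0, 0.0, sigma_mean=1.0)
        b = make_summary("B", 2.3, 0.0, sigma_mean=2.0)
        pooled = np.sqrt(0.5 * (1.0 + 4.0))
        assert effect_size(a, b, denominator="pooled") == pytest.approx(0.3 / pooled)

    def test_collapsed_conventions(self):
        a = make_summary("A", 1.0, 0.0, sigma_mean=0.0)
        b_same = make_summary("B", 1.0, 0.0, sigma_mean=0.0)
        b_diff = make_summary("B", 2.0, 0.0, sigma_mean=0.0)
        assert effect_size(a, b_same) == 0.0
        assert effect_size(a, b_diff) == np.inf

    def test_unknown_denominator(self):
        a = make_summary("A", 1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            effect_size(a, a, denominator="nope")


class TestProbDominance:
    def test_closed_form_oracle(self):
        # predictive difference ~ Normal(-0.2, 0.2^2 + 0.2^2)
        a = make_summary("A", 2.0, 0.0, sigma_mean=0.2)
        b = make_summary("B", 2.2, 0.0, sigma_mean=0.2)
        expected = norm.cdf(-0.2 / np.sqrt(0.08))
        assert prob_dominance(a, b, rng=0) == pytest.approx(expected, abs=0.005)

    def test_complement_identity(self):
        # posterior-draw seeds deliberately disjoint from the predictive rng
        # seeds, otherwise the predictive noise reuses the draw stream
        a = make_summary("A", 1.0, 0.05, sigma_mean=0.3, seed=101)
        b = make_summary("B", 1.2, 0.05, sigma_mean=0.3, seed=202)
        p_ab = prob_dominance(a, b, rng=0)
        p_ba = prob_dominance(b, a, rng=1)
        assert p_ab + p_ba == pytest.approx(1.0, abs=0.01)

    def test_self_comparison_is_half(self):
        a = make_summary("A", 1.0, 0.0, sigma_mean=0.0)
        assert prob_dominance(a, a, rng=0) == pytest.approx(0.5)


class TestProbDirection:
    def test_closed_form_oracle(self):
        # mu_A - mu_B ~ Normal(-0.05, 0.1^2 + 0.1^2)
        a = make_summary("A", 2.0, 0.1, sigma_mean=0.2, seed=3)
        b = make_summary("B", 2.05, 0.1, sigma_mean=0.2, seed=4)
        expected = norm.cdf(0.05 / np.sqrt(0.02))  # the larger branch
        assert prob_direction(a, b) == pytest.approx(expected, abs=0.01)

    def test_symmetric_and_at_least_half(self, rng):
        for _ in range(10):
            a = make_summary("A", rng.uniform(0, 1), 0.1, 0.2,
                             shape=(2, 4000), seed=int(rng.integers(1e6)))
            b = make_summary("B", rng.uniform(0, 1), 0.1, 0.2,
                             shape=(2, 4000), seed=int(rng.integers(1e6)))
            d = prob_direction(a, b)
            assert d >= 0.5
            assert d == prob_direction(b, a)

    def test_ties_count_half(self):
        a = make_summary("A", 1.0, 0.0, sigma_mean=0.0)
        assert prob_direction(a, a) == pytest.approx(0.5)


class TestSimilarityVerdict:
    def test_two_of_three_logic(self):
        def verdict(effect, pi_d, d_pi):
            return similarity_verdict(("A", "B"), 0.0, effect, pi_d, d_pi)

        assert verdict(0.1, 0.5, 0.55).similar        # 3 of 3
        assert verdict(0.1, 0.5, 0.9).similar         # 2 of 3
        assert verdict(0.7, 0.5, 0.55).similar        # 2 of 3
        assert not verdict(0.7, 0.9, 0.55).similar    # 1 of 3
        assert not verdict(0.7, 0.9, 0.9).similar     # 0 of 3

    def test_rounding_before_comparison(self):
        v = similarity_verdict(("A", "B"), 0.0, effect=0.34, pi_d=0.44,
                               d_pi=0.64)
        # 0.34 -> 0.3 passes; 0.44 -> 0.4 passes; 0.64 -> 0.6 passes
        assert v.c1 and v.c2 and v.c3 and v.similar

    def test_inclusive_band_edges(self):
        v = similarity_verdict(("A", "B"), 0.0, effect=0.3, pi_d=0.4, d_pi=0.6)
        assert v.c1 and v.c2 and v.c3

    def test_infinite_effect_fails_criterion(self):
        v = similarity_verdict(("A", "B"), 1.0, effect=float("inf"),
                               pi_d=0.5, d_pi=0.5)
        assert not v.c1 and v.similar  # c2 + c3 still carry the verdict


class TestAssessPair:
    def test_identical_posteriors_similar(self):
        a = make_summary("A", 0.08, 0.005, sigma_mean=0.02, seed=5)
        out = assess_pair(a, a, rng=0)
        assert out.similar
        assert out.d_mu == 0.0
        assert out.effect_size == 0.0
        assert out.pi_d == pytest.approx(0.5, abs=0.01)

    def test_well_separated_pairs_rarely_similar(self):
        """Pairs whose EAPs sit many posterior SDs apart must be called
        similar in at most 10% of runs (checked over 15 seeds)."""
        hits = 0
        total = 0
        for seed in range(15):
            gen = np.random.default_rng(seed)
            y_a = gen.normal(1.0, 0.2, size=6)
            y_b = gen.normal(2.0, 0.2, size=6)
            cfg_a = McmcConfig(n_chains=2, n_draws=800, n_warmup=300,
                               seed=2 * seed)
            cfg_b = McmcConfig(n_chains=2, n_draws=800, n_warmup=300,
                               seed=2 * seed + 1)
            a = fit_posterior(trim_outliers(y_a), cfg_a, molecule_id="A")
            b = fit_posterior(trim_outliers(y_b), cfg_b, molecule_id="B")
            if abs(a.eap_mu - b.eap_mu) < 5 * a.post_sd:
                continue  # only count genuinely well-separated draws
            total += 1
            hits += assess_pair(a, b, rng=seed).similar
        assert total >= 10
        assert hits / total <= 0.10
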