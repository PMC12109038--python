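"""Noise-floor likelihood, mixture posterior, and numerical KL divergences."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from wundtgain import (
    GaussianBelief,
    ModelSetup,
    NoisyLikelihood,
    ParameterError,
    augmented_evidence,
    bs_closed,
    bs_mixture,
    evidence_kernel,
    kl_gaussians,
    kl_numeric,
    kld_closed,
    kld_mixture,
    mixture_pdf,
    mixture_posterior,
    mixture_surprise,
    mixture_weights,
)


def make_setup(prior_var, lik_var, delta=0.0):
    return ModelSetup(
        prior=GaussianBelief(mean=0.0, variance=prior_var),
        lik_variance=lik_var,
        prediction_error=delta,
    )


class TestAugmentedEvidence:
    def test_normalizer_cancels_at_peak(self):
        setup = make_setup(10.0, 1.0, 0.0)
        noise = NoisyLikelihood(1.0, 1e-3)
        assert augmented_evidence(setup, noise) == pytest.approx(1.0, abs=1e-15)

    def test_floor_at_large_error(self):
        setup = make_setup(10.0, 1.0, 500.0)
        noise = NoisyLikelihood(1.0, 1e-3)
        assert augmented_evidence(setup, noise) == pytest.approx(1e-3 / 1.001, rel=1e-9)

    def test_dominates_scaled_noise_free_evidence(self):
        noise = NoisyLikelihood(1.0, 1e-3)
        for d in [0.0, 2.0, 10.0, 30.0]:
            setup = make_setup(10.0, 1.0, d)
            assert augmented_evidence(setup, noise) >= noise.alpha * evidence_kernel(setup)

    def test_inconsistent_lik_variance_rejected(self):
        with pytest.raises(ParameterError):
            augmented_evidence(make_setup(10.0, 2.0), NoisyLikelihood(1.0, 1e-3))


class TestMixtureSurprise:
    def test_zero_at_zero_error(self):
        assert mixture_surprise(make_setup(10.0, 1.0, 0.0), NoisyLikelihood(1.0, 1e-3)) == 0.0

    def test_saturation(self):
        noise = NoisyLikelihood(1.0, 1e-3)
        s = mixture_surprise(make_setup(10.0, 1.0, 1000.0), noise)
        assert s == pytest.approx(math.log(1001.0), rel=1e-9)
        assert s < noise.surprise_ceiling + 1e-12

    def test_monotone_in_prediction_error(self):
        noise = NoisyLikelihood(1.0, 1e-3)
        deltas = np.linspace(0.0, 50.0, 200)
        vals = [mixture_surprise(make_setup(10.0, 1.0, d), noise) for d in deltas]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestMixtureWeights:
    def test_near_total_posterior_dominance_at_zero_error(self):
        w_post, w_pri = mixture_weights(make_setup(10.0, 1.0, 0.0), NoisyLikelihood(1.0, 1e-3))
        assert w_post == pytest.approx(1.0 / 1.001, rel=1e-12)
        assert w_post + w_pri == 1.0

    def test_equal_weights_at_switchover(self):
        # e(delta) = eps exactly at delta = sqrt(2 total ln(1/eps))
        eps = 1e-3
        total = 11.0
        delta = math.sqrt(2.0 * total * math.log(1.0 / eps))
        w_post, w_pri = mixture_weights(make_setup(10.0, 1.0, delta), NoisyLikelihood(1.0, eps))
        assert w_post == pytest.approx(0.5, abs=1e-12)
        assert w_pri == pytest.approx(0.5, abs=1e-12)

    def test_prior_takes_over_at_large_error(self):
        _, w_pri = mixture_weights(make_setup(10.0, 1.0, 100.0), NoisyLikelihood(1.0, 1e-3))
        assert w_pri > 1.0 - 1e-12

    def test_switch_is_monotone(self):
        noise = NoisyLikelihood(1.0, 1e-3)
        deltas = np.linspace(0.0, 40.0, 100)
        w = [mixture_weights(make_setup(10.0, 1.0, d), noise) for d in deltas]
        w_post = [x[0] for x in w]
        assert all(a >= b for a, b in zip(w_post, w_post[1:]))


class TestMixturePdf:
    @pytest.mark.parametrize("delta", [0.0, 5.0, 12.0, 30.0])
    def test_normalizes(self, delta):
        setup = make_setup(10.0, 1.0, delta)
        mp = mixture_posterior(setup, NoisyLikelihood(1.0, 1e-3))
        lo = min(mp.pri.mean, mp.post.mean) - 14 * mp.pri.std
        hi = max(mp.pri.mean, mp.post.mean) + 14 * mp.pri.std
        mass, _ = quad(lambda s: mixture_pdf(s, mp), lo, hi, limit=300,
                       points=[mp.pri.mean, mp.post.mean])
        assert mass == pytest.approx(1.0, abs=1e-8)

    def test_degenerate_weights(self):
        from wundtgain import MixturePosterior

        post = GaussianBelief(1.0, 0.5)
        pri = GaussianBelief(0.0, 10.0)
        only_post = MixturePosterior(w_post=1.0, w_pri=0.0, post=post, pri=pri)
        only_pri = MixturePosterior(w_post=0.0, w_pri=1.0, post=post, pri=pri)
        for s in [-2.0, 0.0, 1.3]:
            assert mixture_pdf(s, only_post) == pytest.approx(post.pdf(s), rel=1e-14)
            assert mixture_pdf(s, only_pri) == pytest.approx(pri.pdf(s), rel=1e-14)

    def test_weights_must_sum_to_one(self):
        from wundtgain import MixturePosterior

        with pytest.raises(ParameterError):
            MixturePosterior(w_post=0.6, w_pri=0.6,
                             post=GaussianBelief(0, 1), pri=GaussianBelief(0, 1))


class TestKlNumeric:
    def test_identical_densities(self):
        p = GaussianBelief(0.7, 2.0)
        assert kl_numeric(p.pdf, p.pdf, (-20, 20)) == pytest.approx(0.0, abs=1e-9)

    def test_matches_gaussian_closed_form(self):
        p = GaussianBelief(0.0, 1.0)
        q = GaussianBelief(1.0, 1.0)
        assert kl_numeric(p.pdf, q.pdf, (-15, 16)) == pytest.approx(0.5, abs=1e-10)
        # and an unequal-variance pair against the closed form
        r = GaussianBelief(-0.5, 3.0)
        assert kl_numeric(p.pdf, r.pdf, (-25, 25)) == pytest.approx(
            kl_gaussians(p, r), abs=1e-10
        )

    def test_prior_against_degenerate_mixture(self):
        setup = make_setup(10.0, 1.0, 3.0)
        mp = mixture_posterior(setup, NoisyLikelihood(1.0, 1e-3))
        from wundtgain import MixturePosterior

        degen = MixturePosterior(w_post=0.0, w_pri=1.0, post=mp.post, pri=mp.pri)
        assert kl_numeric(setup.prior.pdf, degen.pdf, (-40, 40)) == pytest.approx(
            0.0, abs=1e-9
        )


# variance combos where the vanishing-floor limit converges fast
# (likelihood at least as wide as the prior)
ORACLE_COMBOS = [(0.5, 1.0), (1.0, 2.0), (1.0, 5.0), (2.0, 10.0), (1.0, 50.0)]


class TestMixtureGains:
    @pytest.mark.parametrize("sp2,sl2", ORACLE_COMBOS)
    def test_vanishing_floor_recovers_closed_forms(self, sp2, sl2):
        noise = NoisyLikelihood(sl2, 1e-12)
        for frac in [0.0, 0.5, 1.0]:
            delta = frac * 3.0 * math.sqrt(sp2 + sl2)
            setup = make_setup(sp2, sl2, delta)
            assert kld_mixture(setup, noise) == pytest.approx(kld_closed(setup), abs=1e-6)
            assert bs_mixture(setup, noise) == pytest.approx(bs_closed(setup), abs=1e-6)

    def test_bs_oracle_holds_even_for_wide_prior(self):
        # the mixture Bayesian surprise converges fast regardless of the
        # variance ratio (its outer density has the thin posterior tails)
        noise = NoisyLikelihood(1.0, 1e-12)
        for delta in [0.0, 3.0, 8.0]:
            setup = make_setup(10.0, 1.0, delta)
            assert bs_mixture(setup, noise) == pytest.approx(bs_closed(setup), abs=1e-6)

    def test_kld_floor_gap_shrinks_with_eps_for_wide_prior(self):
        # for a prior wider than the likelihood the floor caps the prior-tail
        # contribution to KLD; the gap to the closed form decays like
        # eps**(lik_var/prior_var) and so is still visible at eps=1e-12
        setup = make_setup(10.0, 1.0, 1.5)
        gaps = [
            abs(kld_mixture(setup, NoisyLikelihood(1.0, eps)) - kld_closed(setup))
            for eps in (1e-3, 1e-6, 1e-12)
        ]
        assert gaps[0] > gaps[1] > gaps[2] > 1e-6

    def test_gains_vanish_at_large_error(self):
        noise = NoisyLikelihood(1.0, 1e-3)
        setup = make_setup(10.0, 1.0, 50.0)
        assert kld_mixture(setup, noise) < 1e-6
        assert bs_mixture(setup, noise) < 1e-6

    def test_bs_decay_lags_evidence_by_a_log_factor(self):
        # BS ~ w_post * (quadratic in delta), so right at the point where
        # e(delta) = eps * 1e-6 it still sits a small log factor above 1e-6
        # and only drops below further out
        eps = 1e-3
        noise = NoisyLikelihood(1.0, eps)
        delta_star = math.sqrt(2.0 * 11.0 * math.log(1.0 / (eps * 1e-6)))
        at_threshold = bs_mixture(make_setup(10.0, 1.0, delta_star), noise)
        assert 1e-6 < at_threshold < 1e-5
        assert bs_mixture(make_setup(10.0, 1.0, 1.3 * delta_star), noise) < 1e-6

    def test_small_error_increases_gains(self):
        noise = NoisyLikelihood(1.0, 1e-3)
        k0 = kld_mixture(make_setup(10.0, 1.0, 0.0), noise)
        k1 = kld_mixture(make_setup(10.0, 1.0, 1.0), noise)
        b0 = bs_mixture(make_setup(10.0, 1.0, 0.0), noise)
        b1 = bs_mixture(make_setup(10.0, 1.0, 1.0), noise)
        assert k1 > k0 and b1 > b0

    def test_divergences_are_asymmetric(self):
        noise = NoisyLikelihood(1.0, 1e-3)
        setup = make_setup(10.0, 1.0, 6.0)
        assert kld_mixture(setup, noise) != pytest.approx(bs_mixture(setup, noise), abs=1e-3)
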