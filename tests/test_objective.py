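"""Distortion, rate, mutual information and the ELBO identity."""

import numpy as np
import pytest
from scipy import integrate

from popcode import (
    DecoderParams,
    EncoderParams,
    IsingParams,
    PatternTable,
    StimulusDistribution,
    distortion,
    kl_stimulus_generative,
    lagrangian,
    mutual_information,
    neg_elbo,
    pattern_log_probs,
    prior_log_probs,
    rate,
)
from popcode.decoder import generative_marginal_log_density
from popcode.objective import ObjectiveValues, conditional_log_density_table
from tests.conftest import constant_decoder, random_decoder, random_encoder, random_ising


def flat_encoder(n, width=1e9):
    """Encoder whose spike probabilities are (almost) stimulus independent."""
    return EncoderParams(np.ones(n), np.zeros(n), np.full(n, width))


class TestDistortion:
    def test_constant_decoder_equal_to_stimulus_distribution(self):
        # decoder that ignores r and reproduces pi exactly: D = <-log pi>,
        # whose expectation is the stimulus entropy
        dist = StimulusDistribution.gaussian(0.0, 5.0)
        x = dist.sample(40_000, seed=0)
        dec = constant_decoder(3, "gaussian", mu=0.0, sigma2=5.0)
        enc = random_encoder(np.random.default_rng(1), 3)
        d = distortion(enc, dec, PatternTable(3), x)
        se = np.std(dist.log_density(x)) / np.sqrt(x.size)
        assert d == pytest.approx(dist.entropy(), abs=3 * se + 1e-3)

    def test_matches_brute_force_four_term_sum(self, rng):
        tbl = PatternTable(2)
        enc = random_encoder(rng, 2)
        dec = random_decoder(rng, 2)
        xs = rng.normal(0, 1, 5)
        total = 0.0
        for x in xs:
            q = np.exp(pattern_log_probs(enc, float(x), tbl))
            ll = conditional_log_density_table(dec, tbl, [float(x)])[0]
            total += -np.dot(q, ll)
        assert distortion(enc, dec, tbl, xs) == pytest.approx(
            total / xs.size, rel=1e-10
        )

    def test_empty_batch_raises(self, rng):
        with pytest.raises(ValueError):
            distortion(
                random_encoder(rng, 2), random_decoder(rng, 2), PatternTable(2), []
            )


class TestRate:
    def test_zero_when_encoder_matches_prior(self):
        enc = flat_encoder(3)
        prior = IsingParams(np.zeros(3), np.zeros((3, 3)))
        r = rate(enc, prior, PatternTable(3), np.linspace(-2, 2, 9))
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_spike_against_fair_prior(self):
        # single neuron that always spikes vs Bernoulli(1/2) prior: KL = ln 2
        enc = EncoderParams([1e12], [0.0], [1e6])
        prior = IsingParams([0.0], np.zeros((1, 1)))
        assert rate(enc, prior, PatternTable(1), [0.0]) == pytest.approx(
            np.log(2), rel=1e-9
        )

    def test_nonnegative_on_random_models(self, rng):
        for _ in range(20):
            enc = random_encoder(rng, 3)
            prior = random_ising(rng, 3)
            assert rate(enc, prior, PatternTable(3), rng.normal(0, 2, 8)) >= 0

    def test_minimized_at_marginal_encoding_prior(self, rng):
        # With N=2 the Ising family spans all distributions over the 4
        # patterns, so the rate-optimal prior (the marginal encoder) is
        # attainable exactly; no perturbation may decrease the rate.
        tbl = PatternTable(2)
        enc = random_encoder(rng, 2)
        xs = rng.normal(0, 2, 30)
        from popcode import marginal_encoding

        q = marginal_encoding(enc, xs, tbl)
        h1 = np.log(q[1] / q[0])
        h2 = np.log(q[2] / q[0])
        j12 = 0.5 * np.log(q[3] * q[0] / (q[1] * q[2]))
        j = np.array([[0.0, j12], [j12, 0.0]])
        star = IsingParams([h1, h2], j)
        np.testing.assert_allclose(np.exp(prior_log_probs(star, tbl)), q, rtol=1e-9)
        r_star = rate(enc, star, tbl, xs)
        for _ in range(50):
            dj = j12 + rng.normal(0, 0.1)
            pert = IsingParams(
                np.array([h1, h2]) + rng.normal(0, 0.1, 2),
                np.array([[0.0, dj], [dj, 0.0]]),
            )
            assert rate(enc, pert, tbl, xs) >= r_star - 1e-12


class TestLagrangian:
    def test_equals_distortion_when_constraint_active(self):
        v = ObjectiveValues(distortion=1.2, rate=0.8, beta=1.0, target_rate=0.8)
        assert lagrangian(v) == pytest.approx(1.2)

    def test_beta_zero_ignores_rate(self):
        v = ObjectiveValues(distortion=1.2, rate=5.0, beta=0.0, target_rate=0.1)
        assert lagrangian(v) == pytest.approx(1.2)

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            lagrangian(ObjectiveValues(1.0, 1.0, beta=-0.5, target_rate=0.0))

    def test_neg_elbo_identity(self, rng):
        enc = random_encoder(rng, 2)
        dec = random_decoder(rng, 2)
        prior = random_ising(rng, 2)
        tbl = PatternTable(2)
        xs = rng.normal(0, 1, 6)
        v = neg_elbo(enc, dec, prior, tbl, xs)
        assert v.neg_elbo == pytest.approx(v.distortion + v.rate, rel=1e-14)


class TestMutualInformation:
    def test_zero_for_stimulus_independent_encoder(self):
        enc = flat_encoder(3)
        mi = mutual_information(enc, PatternTable(3), np.linspace(-1, 1, 20))
        assert mi == pytest.approx(0.0, abs=1e-10)

    def test_deterministic_binary_split_gives_ln2(self):
        # one steep neuron that spikes iff x > 0, stimuli split 50/50
        # a neuron centered at +1, narrow enough that it spikes with
        # probability ~1 at x=+1 and ~0 at x=-1
        enc = EncoderParams([1e6], [1.0], [0.25])
        xs = np.array([-1.0, 1.0] * 25)
        mi = mutual_information(enc, PatternTable(1), xs)
        assert mi == pytest.approx(np.log(2), rel=1e-3)

    def test_sandwich_bounds_on_random_models(self, rng):
        # H(pi) - D <= I <= R with empirical-batch semantics
        dist = StimulusDistribution.gaussian(0.0, 2.0)
        tbl = PatternTable(3)
        xs = dist.sample(400, seed=9)
        for _ in range(30):
            enc = random_encoder(rng, 3)
            prior = random_ising(rng, 3)
            dec = random_decoder(rng, 3)
            mi = mutual_information(enc, tbl, xs)
            d = distortion(enc, dec, tbl, xs)
            r = rate(enc, prior, tbl, xs)
            assert mi <= r + 1e-9
            assert dist.entropy() - d <= mi + 0.05  # MC slack on H - D


class TestKLStimulusGenerative:
    def test_zero_when_generative_equals_stimulus(self, rng):
        dist = StimulusDistribution.gaussian(0.0, 5.0)
        dec = constant_decoder(2, "gaussian", mu=0.0, sigma2=5.0)
        prior = random_ising(rng, 2)
        kl, se = kl_stimulus_generative(dist, dec, prior, PatternTable(2), 5000, 1)
        assert abs(kl) < 3 * se + 1e-4

    def test_two_gaussians_closed_form(self, rng):
        dist = StimulusDistribution.gaussian(0.5, 2.0)
        dec = constant_decoder(2, "gaussian", mu=-0.3, sigma2=3.0)
        prior = random_ising(rng, 2)
        kl, se = kl_stimulus_generative(dist, dec, prior, PatternTable(2), 20000, 2)
        expected = 0.5 * (np.log(3.0 / 2.0) + (2.0 + (0.5 + 0.3) ** 2) / 3.0 - 1)
        assert kl == pytest.approx(expected, abs=3 * se)


class TestElboIdentity:
    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_joint_kl_decomposition(self, rng, n):
        """D + R - H(pi) = KL(pi || p(x)) + <KL(q(r|x) || p(r|x))>_pi.

        Both sides evaluated by quadrature over x and exact enumeration
        over patterns; this is the chain-rule decomposition of the joint
        KL between recognition and generative models.
        """
        dist = StimulusDistribution.gaussian(0.2, 1.5)
        tbl = PatternTable(n)
        enc = random_encoder(rng, n)
        dec = random_decoder(rng, n)
        prior = random_ising(rng, n, scale=0.3)
        log_p_r = prior_log_probs(prior, tbl)

        grid = np.linspace(-8, 8, 3001)
        pi = dist.density(grid)
        log_pi = dist.log_density(grid)
        log_q = pattern_log_probs(enc, grid, tbl)  # (G, P)
        q = np.exp(log_q)
        ll = conditional_log_density_table(dec, tbl, grid)  # (G, P)
        log_px = generative_marginal_log_density(dec, prior, tbl, grid)

        d_x = -np.sum(q * ll, axis=1)
        r_x = np.sum(q * (log_q - log_p_r), axis=1)
        lhs = integrate.trapezoid(pi * (d_x + r_x + log_pi), grid)

        # generative posterior p(r|x) = p(x|r) p(r) / p(x)
        log_post = ll + log_p_r - log_px[:, None]
        kl_post = np.sum(q * (log_q - log_post), axis=1)
        rhs = integrate.trapezoid(pi * (log_pi - log_px), grid) + integrate.trapezoid(
            pi * kl_post, grid
        )
        assert lhs == pytest.approx(rhs, abs=1e-3)
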