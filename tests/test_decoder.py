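"""Decoder network, conditional densities, MAP and generative marginal."""

import numpy as np
import pytest
from scipy import integrate

from popcode import (
    DecoderParams,
    IsingParams,
    PatternTable,
    conditional_log_density,
    decode,
    generative_marginal_log_density,
    map_estimate,
    sample_estimate,
)
from popcode.decoder import decode_single
from tests.conftest import constant_decoder, random_decoder, random_ising


class TestDecode:
    def test_constant_network_maps_all_patterns_to_biases(self, tbl3):
        dec = constant_decoder(3, "gaussian", mu=1.5, sigma2=0.7)
        mu, sigma2 = decode(dec, tbl3)
        np.testing.assert_allclose(mu, 1.5)
        np.testing.assert_allclose(sigma2, 0.7, rtol=1e-5)

    def test_matches_independent_matrix_arithmetic(self, rng, tbl3):
        # oracle: re-implement the two-layer map with plain matrix algebra
        dec = random_decoder(rng, 3)
        mu, sigma2 = decode(dec, tbl3)
        for k, r in enumerate(tbl3.patterns):
            hid = np.tanh(dec.w1 @ r + dec.b1)
            out = dec.w2 @ hid + dec.b2
            assert mu[k] == pytest.approx(out[0], rel=1e-12)
            assert sigma2[k] == pytest.approx(
                np.exp(out[1]) + dec.sigma2_floor, rel=1e-12
            )

    def test_decode_single_agrees_with_table(self, rng, tbl3):
        dec = random_decoder(rng, 3)
        mu, sigma2 = decode(dec, tbl3)
        m, s2 = decode_single(dec, tbl3.patterns[5])
        assert (m, s2) == (pytest.approx(mu[5]), pytest.approx(sigma2[5]))

    def test_variances_always_positive(self, rng, tbl3):
        dec = random_decoder(rng, 3)
        dec.b2[1] = -200.0  # drive raw log-variance far negative
        _, sigma2 = decode(dec, tbl3)
        assert np.all(sigma2 > 0)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            decode(random_decoder(rng, 3), PatternTable(4))


class TestConditionalLogDensity:
    def test_gaussian_peak_value(self, tbl3):
        dec = constant_decoder(3, "gaussian", mu=2.0, sigma2=0.5)
        r = tbl3.patterns[0]
        _, s2 = decode_single(dec, r)
        assert conditional_log_density(dec, 2.0, r) == pytest.approx(
            -0.5 * np.log(2 * np.pi * s2)
        )

    def test_lognormal_at_exp_mu(self, tbl3):
        mu, s2 = 0.8, 0.3
        dec = constant_decoder(3, "lognormal", mu=mu, sigma2=s2)
        r = tbl3.patterns[1]
        _, s2f = decode_single(dec, r)
        assert conditional_log_density(dec, np.exp(mu), r) == pytest.approx(
            -mu - 0.5 * np.log(2 * np.pi * s2f)
        )

    def test_lognormal_nonpositive_stimulus(self, tbl3):
        dec = constant_decoder(3, "lognormal", mu=0.0, sigma2=1.0)
        assert conditional_log_density(dec, -2.0, tbl3.patterns[0]) == -np.inf
        assert conditional_log_density(dec, 0.0, tbl3.patterns[0]) == -np.inf

    @pytest.mark.parametrize("family", ["gaussian", "lognormal"])
    def test_density_integrates_to_one(self, rng, tbl3, family):
        dec = random_decoder(rng, 3, family=family)
        r = tbl3.patterns[3]
        lo = 1e-9 if family == "lognormal" else -np.inf
        val, _ = integrate.quad(
            lambda x: np.exp(conditional_log_density(dec, x, r)), lo, np.inf,
            limit=400,
        )
        assert val == pytest.approx(1.0, abs=1e-6)


class TestMapEstimate:
    def test_gaussian_returns_mean(self, tbl3):
        dec = constant_decoder(3, "gaussian", mu=3.0, sigma2=1.0)
        assert map_estimate(dec, tbl3.patterns[0]) == pytest.approx(3.0)

    def test_lognormal_small_variance_limit(self, tbl3):
        dec = constant_decoder(3, "lognormal", mu=1.2, sigma2=1e-6)
        assert map_estimate(dec, tbl3.patterns[0]) == pytest.approx(
            np.exp(1.2), rel=1e-4
        )

    def test_lognormal_default_matches_grid_argmax(self, tbl3):
        # oracle: brute-force argmax of the closed-form density on a fine grid
        dec = constant_decoder(3, "lognormal", mu=0.0, sigma2=1.0)
        r = tbl3.patterns[0]
        grid = np.linspace(1e-3, 3.0, 200_001)
        dens = conditional_log_density(dec, grid, r)
        argmax = grid[np.argmax(dens)]
        assert map_estimate(dec, r) == pytest.approx(np.exp(-1.0), rel=1e-4)
        assert map_estimate(dec, r) == pytest.approx(argmax, rel=1e-3)

    def test_lognormal_literal_mode(self, tbl3):
        dec = constant_decoder(3, "lognormal", mu=0.5, sigma2=0.2)
        dec.map_mode = "literal"
        _, s2 = decode_single(dec, tbl3.patterns[0])
        assert map_estimate(dec, tbl3.patterns[0]) == pytest.approx(
            np.exp(0.5 - 2 * s2)
        )


class TestSampleEstimate:
    def test_gaussian_degenerate_returns_mean(self, tbl3):
        dec = constant_decoder(3, "gaussian", mu=-1.0, sigma2=1e-12)
        # the variance floor (1e-6) dominates the requested 1e-12 here
        assert sample_estimate(dec, tbl3.patterns[0], seed=0) == pytest.approx(
            -1.0, abs=5e-3
        )

    def test_moments_match(self, tbl3):
        dec = constant_decoder(3, "gaussian", mu=0.7, sigma2=2.0)
        draws = np.array(
            [sample_estimate(dec, tbl3.patterns[0], seed=s) for s in range(3000)]
        )
        assert draws.mean() == pytest.approx(0.7, abs=3 * np.sqrt(2.0 / 3000))

    def test_lognormal_draws_positive(self, rng, tbl3):
        dec = random_decoder(rng, 3, family="lognormal")
        draws = [sample_estimate(dec, tbl3.patterns[2], seed=s) for s in range(200)]
        assert np.all(np.array(draws) > 0)


class TestGenerativeMarginal:
    def test_constant_decoder_collapses_mixture(self, rng, tbl3):
        dec = constant_decoder(3, "gaussian", mu=0.3, sigma2=1.1)
        prior = random_ising(rng, 3)
        x = np.linspace(-3, 3, 11)
        got = generative_marginal_log_density(dec, prior, tbl3, x)
        expected = conditional_log_density(dec, x, tbl3.patterns[0])
        np.testing.assert_allclose(got, expected, rtol=1e-10)

    def test_symmetric_two_component_mixture_is_even(self):
        tbl = PatternTable(1)
        mu = 1.4
        dec = DecoderParams(
            family="gaussian",
            w1=np.array([[40.0]]),
            b1=np.array([-20.0]),
            w2=np.array([[mu], [0.0]]),
            b2=np.array([0.0, 0.0]),
        )
        # tanh(-20) ~ -1, tanh(20) ~ 1: the two patterns decode to -/+ mu
        prior = IsingParams([0.0], np.zeros((1, 1)))
        x = np.linspace(0.1, 2.5, 8)
        left = generative_marginal_log_density(dec, prior, tbl, -x)
        right = generative_marginal_log_density(dec, prior, tbl, x)
        np.testing.assert_allclose(left, right, rtol=1e-6)

    def test_matches_brute_force_four_term_sum(self, rng):
        tbl = PatternTable(2)
        dec = random_decoder(rng, 2)
        prior = random_ising(rng, 2)
        from popcode import prior_log_probs

        p = np.exp(prior_log_probs(prior, tbl))
        for x in (-1.2, 0.4, 2.2):
            direct = sum(
                p[k] * np.exp(conditional_log_density(dec, x, tbl.patterns[k]))
                for k in range(4)
            )
            got = generative_marginal_log_density(dec, prior, tbl, np.array(x))
            assert got == pytest.approx(np.log(direct), rel=1e-10)

    def test_mixture_bounds(self, rng, tbl3):
        dec = random_decoder(rng, 3)
        prior = random_ising(rng, 3)
        x = np.array([0.5])
        comps = np.array(
            [conditional_log_density(dec, 0.5, r) for r in tbl3.patterns]
        )
        val = generative_marginal_log_density(dec, prior, tbl3, x)[0]
        assert comps.min() - 1e-9 <= val <= comps.max() + 1e-9

    def test_no_overflow_for_extreme_logits(self, tbl3):
        dec = constant_decoder(3, "gaussian", mu=0.0, sigma2=1.0)
        prior = IsingParams(np.full(3, 200.0), np.zeros((3, 3)))
        val = generative_marginal_log_density(dec, prior, tbl3, np.array([1e3]))
        assert np.isfinite(val)

    @pytest.mark.parametrize("family", ["gaussian", "lognormal"])
    def test_marginal_integrates_to_one(self, rng, family):
        tbl = PatternTable(2)
        dec = random_decoder(rng, 2, family=family)
        prior = random_ising(rng, 2)
        lo = 1e-9 if family == "lognormal" else -np.inf
        val, _ = integrate.quad(
            lambda x: np.exp(
                generative_marginal_log_density(dec, prior, tbl, np.array(x))
            ),
            lo,
            np.inf,
            limit=400,
        )
        assert val == pytest.approx(1.0, abs=1e-4)
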