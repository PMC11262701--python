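"""Distortion, rate, ELBO, mutual information and related divergences.

All expectations over patterns are exact sums over the enumerated 2^N
patterns; expectations over stimuli are empirical averages over the
supplied batch (identical semantics in training and evaluation).  All
quantities are in nats.

Nomenclature (rate-distortion):

* distortion  D = < -sum_r q(r|x) log p(x|r) >_pi
* rate        R = < KL(q(r|x) || p(r)) >_pi  >= 0
* -ELBO       = D + R
* Lagrangian  L = D + beta (R - Rbar), the objective of the constrained
  problem  min D  s.t.  R <= Rbar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .decoder import DecoderParams, decode, gaussian_log_density, lognormal_log_density
from .encoder import EncoderParams, PatternTable, pattern_log_probs
from .ising import IsingParams, prior_log_probs


@dataclass
class ObjectiveValues:
    """One evaluation of the training objective."""

    distortion: float
    rate: float
    beta: float = 1.0
    target_rate: float = 0.0

    @property
    def neg_elbo(self) -> float:
        return self.distortion + self.rate

    @property
    def lagrangian(self) -> float:
        return self.distortion + self.beta * (self.rate - self.target_rate)


def conditional_log_density_table(
    dec: DecoderParams, tbl: PatternTable, stimuli
) -> np.ndarray:
    """log p(x_m | r_k) for a batch; shape (batch, 2^N)."""
    mu, sigma2 = decode(dec, tbl)
    x = np.atleast_1d(np.asarray(stimuli, dtype=float))[:, None]
    if dec.family == "gaussian":
        return gaussian_log_density(x, mu, sigma2)
    return lognormal_log_density(x, mu, sigma2)


def distortion(
    enc: EncoderParams, dec: DecoderParams, tbl: PatternTable, stimuli
) -> float:
    """D = mean_m  -sum_r q(r|x_m) log p(x_m|r)."""
    stimuli = np.atleast_1d(np.asarray(stimuli, dtype=float))
    if stimuli.size == 0:
        raise ValueError("stimulus batch must be nonempty")
    q = np.exp(pattern_log_probs(enc, stimuli, tbl))
    ll = conditional_log_density_table(dec, tbl, stimuli)
    return float(-np.mean(np.sum(q * ll, axis=1)))


def rate(
    enc: EncoderParams, prior: IsingParams, tbl: PatternTable, stimuli
) -> float:
    """R = mean_m  KL(q(r|x_m) || p(r)) >= 0."""
    stimuli = np.atleast_1d(np.asarray(stimuli, dtype=float))
    if stimuli.size == 0:
        raise ValueError("stimulus batch must be nonempty")
    log_q = pattern_log_probs(enc, stimuli, tbl)
    log_p = prior_log_probs(prior, tbl)
    q = np.exp(log_q)
    return float(np.mean(np.sum(q * (log_q - log_p), axis=1)))


def neg_elbo(
    enc: EncoderParams,
    dec: DecoderParams,
    prior: IsingParams,
    tbl: PatternTable,
    stimuli,
) -> ObjectiveValues:
    return ObjectiveValues(
        distortion=distortion(enc, dec, tbl, stimuli),
        rate=rate(enc, prior, tbl, stimuli),
    )


def lagrangian(values: ObjectiveValues) -> float:
    """L = D + beta (R - Rbar); requires beta >= 0."""
    if values.beta < 0:
        raise ValueError("beta must be nonnegative")
    return values.lagrangian


def mutual_information(
    enc: EncoderParams, tbl: PatternTable, stimuli
) -> float:
    """Encoder mutual information I(r; x) with the marginal estimated
    empirically over the batch.

    I = mean_m sum_r q(r|x_m) [log q(r|x_m) - log qbar(r)], with
    qbar(r) = mean_m q(r|x_m).  Satisfies H(pi) - D <= I <= R up to
    Monte-Carlo error.
    """
    stimuli = np.atleast_1d(np.asarray(stimuli, dtype=float))
    if stimuli.size == 0:
        raise ValueError("stimulus batch must be nonempty")
    log_q = pattern_log_probs(enc, stimuli, tbl)
    log_qbar = logsumexp(log_q, axis=0) - np.log(stimuli.size)
    q = np.exp(log_q)
    return float(np.mean(np.sum(q * (log_q - log_qbar), axis=1)))


def kl_stimulus_generative(
    dist,
    dec: DecoderParams,
    prior: IsingParams,
    tbl: PatternTable,
    n_mc: int,
    seed,
    model_log_density=None,
) -> tuple[float, float]:
    """Monte-Carlo estimate of KL(pi(x) || p(x)) and its standard error.

    ``model_log_density`` overrides the generative marginal (used by
    trained models that carry an internal change of variables); default
    is the raw decoder + prior mixture.
    """
    from .decoder import generative_marginal_log_density

    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    x = dist.sample(n_mc, seed)
    if model_log_density is None:
        log_p = generative_marginal_log_density(dec, prior, tbl, x)
    else:
        log_p = model_log_density(x)
    diff = dist.log_density(x) - log_p
    return float(np.mean(diff)), float(np.std(diff, ddof=1) / np.sqrt(n_mc))
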