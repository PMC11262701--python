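"""Generative conditional decoder p(x | r).

A two-layer feed-forward network maps a binary activity pattern r to the
two parameters (location mu(r), log-variance s(r)) of a Gaussian or
log-normal conditional density over stimuli.  The decoded variance is
sigma^2(r) = exp(s(r)) + floor, which keeps it strictly positive; the
second distribution parameter is always a *variance*, never a standard
deviation.

Together with an Ising prior over patterns, the decoder defines the
generative marginal p(x) = sum_r p(x|r) p(r), a 2^N-component mixture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

LOG2PI = float(np.log(2 * np.pi))
_S_CLIP = 60.0  # clip on the log-variance output, guards exp overflow


@dataclass
class DecoderParams:
    """Weights of the two-layer decoder network plus the output family.

    ``family`` is "gaussian" or "lognormal"; ``map_mode`` selects the MAP
    formula for the log-normal family ("standard": exp(mu - sigma^2), the
    mode of the distribution; "literal": exp(mu - 2 sigma^2)).
    """

    family: str
    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    nonlinearity: str = "tanh"
    sigma2_floor: float = 1e-6
    map_mode: str = "standard"

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "lognormal"):
            raise ValueError(f"unknown decoder family {self.family!r}")
        if self.nonlinearity not in ("tanh", "relu"):
            raise ValueError(f"unknown nonlinearity {self.nonlinearity!r}")
        self.w1 = np.asarray(self.w1, dtype=float)
        self.b1 = np.asarray(self.b1, dtype=float)
        self.w2 = np.asarray(self.w2, dtype=float)
        self.b2 = np.asarray(self.b2, dtype=float)
        h, n = self.w1.shape
        if self.b1.shape != (h,) or self.w2.shape != (2, h) or self.b2.shape != (2,):
            raise ValueError("inconsistent decoder weight shapes")

    @property
    def n_inputs(self) -> int:
        return self.w1.shape[1]

    @property
    def hidden_width(self) -> int:
        return self.w1.shape[0]

    @classmethod
    def initialize(
        cls,
        family: str,
        n_inputs: int,
        hidden_width: int = 100,
        nonlinearity: str = "tanh",
        seed=0,
        **kwargs,
    ) -> "DecoderParams":
        """Kaiming-uniform weights (+-sqrt(6/fan_in)), zero biases."""
        rng = np.random.default_rng(seed)
        a1 = np.sqrt(6.0 / n_inputs)
        a2 = np.sqrt(6.0 / hidden_width)
        return cls(
            family=family,
            w1=rng.uniform(-a1, a1, size=(hidden_width, n_inputs)),
            b1=np.zeros(hidden_width),
            w2=rng.uniform(-a2, a2, size=(2, hidden_width)),
            b2=np.zeros(2),
            nonlinearity=nonlinearity,
            **kwargs,
        )


def _activate(dec: DecoderParams, z: np.ndarray) -> np.ndarray:
    return np.tanh(z) if dec.nonlinearity == "tanh" else np.maximum(z, 0.0)


def decode(dec: DecoderParams, tbl) -> tuple[np.ndarray, np.ndarray]:
    """Map every pattern to (mu, sigma^2); each of shape (2^N,)."""
    if tbl.n_neurons != dec.n_inputs:
        raise ValueError("pattern table does not match decoder input width")
    hidden = _activate(dec, tbl.patterns @ dec.w1.T + dec.b1)
    out = hidden @ dec.w2.T + dec.b2
    mu = out[:, 0]
    sigma2 = np.exp(np.clip(out[:, 1], -_S_CLIP, _S_CLIP)) + dec.sigma2_floor
    return mu, sigma2


def decode_single(dec: DecoderParams, r) -> tuple[float, float]:
    """(mu, sigma^2) for one binary pattern."""
    r = np.asarray(r, dtype=float)
    hidden = _activate(dec, dec.w1 @ r + dec.b1)
    out = dec.w2 @ hidden + dec.b2
    sigma2 = float(np.exp(np.clip(out[1], -_S_CLIP, _S_CLIP)) + dec.sigma2_floor)
    return float(out[0]), sigma2


def gaussian_log_density(x, mu, sigma2):
    """log N(x; mu, sigma^2) with broadcasting."""
    return -((np.asarray(x, dtype=float) - mu) ** 2) / (2 * sigma2) - 0.5 * np.log(
        2 * np.pi * sigma2
    )


def lognormal_log_density(x, mu, sigma2):
    """log LN(x; mu, sigma^2); -inf for x <= 0."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        lx = np.where(x > 0, np.log(np.where(x > 0, x, 1.0)), 0.0)
        val = (
            -((lx - mu) ** 2) / (2 * sigma2)
            - lx
            - 0.5 * np.log(2 * np.pi * sigma2)
        )
    return np.where(x > 0, val, -np.inf)


def conditional_log_density(dec: DecoderParams, x, r) -> np.ndarray:
    """log p(x | r) in nats for one pattern r."""
    mu, sigma2 = decode_single(dec, r)
    if dec.family == "gaussian":
        return gaussian_log_density(x, mu, sigma2)
    return lognormal_log_density(x, mu, sigma2)


def map_estimate(dec: DecoderParams, r) -> float:
    """Most probable stimulus under p(x | r)."""
    mu, sigma2 = decode_single(dec, r)
    if dec.family == "gaussian":
        return mu
    factor = 1.0 if dec.map_mode == "standard" else 2.0
    return float(np.exp(mu - factor * sigma2))


def map_estimates(dec: DecoderParams, tbl) -> np.ndarray:
    """MAP estimate for every pattern in the table."""
    mu, sigma2 = decode(dec, tbl)
    if dec.family == "gaussian":
        return mu
    factor = 1.0 if dec.map_mode == "standard" else 2.0
    return np.exp(mu - factor * sigma2)


def sample_estimate(dec: DecoderParams, r, seed) -> float:
    """One stimulus draw from p(x | r)."""
    rng = np.random.default_rng(seed)
    mu, sigma2 = decode_single(dec, r)
    z = rng.normal(mu, np.sqrt(sigma2))
    return float(np.exp(z)) if dec.family == "lognormal" else float(z)


def generative_marginal_log_density(
    dec: DecoderParams, prior, tbl, x
) -> np.ndarray:
    """log p(x) = log sum_r p(x|r) p(r), computed by log-sum-exp."""
    from .ising import prior_log_probs

    mu, sigma2 = decode(dec, tbl)
    x = np.asarray(x, dtype=float)
    if dec.family == "gaussian":
        comp = gaussian_log_density(x[..., None], mu, sigma2)
    else:
        comp = lognormal_log_density(x[..., None], mu, sigma2)
    lp = prior_log_probs(prior, tbl)
    with np.errstate(divide="ignore"):
        return logsumexp(comp + lp, axis=-1)
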