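"""Bernoulli population encoder with Gaussian tuning curves.

Each of N neurons emits at most one spike per coding window.  Neuron i
spikes with probability q(r_i = 1 | x) = logistic(eta_i(x)), where

    eta_i(x) = ln A_i - (x - c_i)^2 / (2 w_i^2)

is the natural parameter of a Bernoulli distribution: A_i is the tuning
amplitude, c_i the preferred stimulus and w_i the tuning width.  With
A_i = 1 the neuron spikes with probability 1/2 at its preferred stimulus.
Conditional on x, neurons are independent, so the population response is
a product Bernoulli distribution over the 2^N binary patterns.

Pattern-indexed quantities use one canonical :class:`PatternTable`:
row k of the table is the binary expansion of the integer k with neuron 0
in the least significant bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, log_expit


@dataclass
class EncoderParams:
    """Tuning-curve parameters {A_i, c_i, w_i} of the Bernoulli encoder."""

    amplitudes: np.ndarray
    centers: np.ndarray
    widths: np.ndarray

    def __post_init__(self) -> None:
        self.amplitudes = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        self.centers = np.atleast_1d(np.asarray(self.centers, dtype=float))
        self.widths = np.atleast_1d(np.asarray(self.widths, dtype=float))
        if not (self.amplitudes.shape == self.centers.shape == self.widths.shape):
            raise ValueError("parameter vectors must share one length N")
        if np.any(self.amplitudes <= 0):
            raise ValueError("amplitudes must be positive")
        if np.any(self.widths <= 0):
            raise ValueError("widths must be positive")

    @property
    def n_neurons(self) -> int:
        return self.amplitudes.size


class PatternTable:
    """All 2^N binary activity patterns in canonical (binary counting) order."""

    def __init__(self, n_neurons: int):
        if n_neurons < 1:
            raise ValueError("need at least one neuron")
        self.n_neurons = n_neurons
        k = np.arange(2**n_neurons, dtype=np.int64)
        self.patterns = ((k[:, None] >> np.arange(n_neurons)) & 1).astype(float)
        self._patterns_f32 = None

    @property
    def patterns_f32(self) -> np.ndarray:
        """Single-precision view used by the fast training path."""
        if self._patterns_f32 is None:
            self._patterns_f32 = self.patterns.astype(np.float32)
        return self._patterns_f32

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[0]

    def index_of(self, r) -> int:
        """Canonical index of a single binary pattern."""
        r = np.asarray(r)
        return int(np.dot(r, 1 << np.arange(self.n_neurons)))


def natural_params(enc: EncoderParams, x) -> np.ndarray:
    """eta_i(x) = ln A_i - (x - c_i)^2 / (2 w_i^2); shape (..., N)."""
    x = np.asarray(x, dtype=float)[..., None]
    return np.log(enc.amplitudes) - (x - enc.centers) ** 2 / (2 * enc.widths**2)


def spike_prob(enc: EncoderParams, x) -> np.ndarray:
    """Per-neuron spiking probability logistic(eta_i(x)); shape (..., N)."""
    return expit(natural_params(enc, x))


def pattern_log_probs(enc: EncoderParams, x, tbl: PatternTable) -> np.ndarray:
    """log q(r | x) over all 2^N patterns; shape (..., 2^N).

    Exponential-family form: log q(r|x) = eta(x)^T r - sum_i softplus(eta_i).
    The exponentials sum to 1 over the pattern table by construction.
    """
    if tbl.n_neurons != enc.n_neurons:
        raise ValueError("pattern table does not match encoder size")
    eta = natural_params(enc, x)
    # softplus(eta) = -log_expit(-eta), stable for large |eta|
    log_norm = np.sum(-log_expit(-eta), axis=-1, keepdims=True)
    return eta @ tbl.patterns.T - log_norm


def sample_patterns(enc: EncoderParams, x: float, n: int, seed) -> np.ndarray:
    """Sample n activity patterns at stimulus x; shape (n, N)."""
    rng = np.random.default_rng(seed)
    q = spike_prob(enc, x)
    return (rng.uniform(size=(n, enc.n_neurons)) < q).astype(float)


def fisher_information(enc: EncoderParams, x) -> np.ndarray:
    """Fisher information J(x) of the Bernoulli encoder.

    For conditionally independent binary neurons this is the variance of
    the score d/dx log q(r|x),

        J(x) = sum_j (x - c_j)^2 / w_j^4 * S(eta_j(x)) (1 - S(eta_j(x))),

    with S the logistic function: each neuron contributes the squared
    slope of its natural parameter times its Bernoulli variance.
    """
    x = np.asarray(x, dtype=float)[..., None]
    eta = np.log(enc.amplitudes) - (x - enc.centers) ** 2 / (2 * enc.widths**2)
    s = expit(eta)
    return np.sum((x - enc.centers) ** 2 / enc.widths**4 * s * (1 - s), axis=-1)


def marginal_encoding(enc: EncoderParams, stimuli, tbl: PatternTable) -> np.ndarray:
    """Empirical marginal q*(r) = mean_m q(r | x_m) over a stimulus batch.

    This is the prior over patterns that minimizes the rate for a fixed
    encoder.
    """
    stimuli = np.atleast_1d(np.asarray(stimuli, dtype=float))
    if stimuli.size == 0:
        raise ValueError("stimulus collection must be nonempty")
    return np.exp(pattern_log_probs(enc, stimuli, tbl)).mean(axis=0)
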