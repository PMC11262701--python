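"""Ising (maximum-entropy) prior over binary activity patterns.

p(r) = exp(h^T r + r^T J r - ln Z), with biases h and a symmetric,
zero-diagonal coupling matrix J.  Everything is computed by exact
enumeration of the 2^N patterns; N is capped (default 20) because the
package deliberately avoids approximate inference.  Setting
``independent`` freezes J at zero, which reduces the prior to a product
of independent Bernoulli distributions (the ablation used to probe the
role of the couplings).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

ENUMERATION_LIMIT = 20


class EnumerationLimitError(RuntimeError):
    """Population too large for the exact enumeration-only design."""


@dataclass
class IsingParams:
    biases: np.ndarray
    couplings: np.ndarray
    independent: bool = False

    def __post_init__(self) -> None:
        self.biases = np.atleast_1d(np.asarray(self.biases, dtype=float))
        self.couplings = np.asarray(self.couplings, dtype=float)
        n = self.biases.size
        if self.couplings.shape != (n, n):
            raise ValueError("couplings must be N x N")
        if self.independent:
            self.couplings = np.zeros((n, n))
        if not np.allclose(self.couplings, self.couplings.T):
            raise ValueError("couplings must be symmetric")
        if np.any(np.diag(self.couplings) != 0):
            raise ValueError("couplings must have zero diagonal")

    @property
    def n_neurons(self) -> int:
        return self.biases.size

    @classmethod
    def independent_bernoulli(cls, biases) -> "IsingParams":
        biases = np.atleast_1d(np.asarray(biases, dtype=float))
        return cls(biases, np.zeros((biases.size, biases.size)), independent=True)


def _check_size(prior: IsingParams, tbl) -> None:
    if prior.n_neurons != tbl.n_neurons:
        raise ValueError("pattern table does not match prior size")
    if prior.n_neurons > ENUMERATION_LIMIT:
        raise EnumerationLimitError(
            f"N={prior.n_neurons} exceeds the exact-enumeration limit "
            f"({ENUMERATION_LIMIT}); this package computes the partition "
            "function by summing all 2^N patterns and provides no sampler "
            "or approximation for larger populations"
        )


def pattern_energies(prior: IsingParams, tbl) -> np.ndarray:
    """Unnormalized log-weights h^T r + r^T J r for every pattern."""
    _check_size(prior, tbl)
    r = tbl.patterns
    return r @ prior.biases + np.einsum("ki,ij,kj->k", r, prior.couplings, r)


def log_partition(prior: IsingParams, tbl) -> float:
    """ln Z = ln sum_r exp(h^T r + r^T J r)."""
    return float(logsumexp(pattern_energies(prior, tbl)))


def prior_log_probs(prior: IsingParams, tbl) -> np.ndarray:
    """log p(r) for every pattern in canonical order; exponentials sum to 1."""
    e = pattern_energies(prior, tbl)
    return e - logsumexp(e)


def prior_entropy(prior: IsingParams, tbl) -> float:
    """-sum_r p log p, in nats; lies in [0, N ln 2]."""
    lp = prior_log_probs(prior, tbl)
    p = np.exp(lp)
    return float(-np.sum(np.where(p > 0, p * lp, 0.0)))


def sample_prior(prior: IsingParams, tbl, n: int, seed) -> np.ndarray:
    """Exact categorical sampling over the enumerated patterns; (n, N)."""
    rng = np.random.default_rng(seed)
    p = np.exp(prior_log_probs(prior, tbl))
    idx = rng.choice(tbl.n_patterns, size=n, p=p / p.sum())
    return tbl.patterns[idx]


def wishart_couplings(n_neurons: int, seed) -> np.ndarray:
    """Random coupling matrix used at initialization.

    Draw G with i.i.d. zero-mean entries of variance 1/N, form the
    Wishart-style product G^T G, then symmetrize and zero the diagonal so
    the result is a valid coupling matrix.
    """
    rng = np.random.default_rng(seed)
    g = rng.normal(scale=1.0 / np.sqrt(n_neurons), size=(n_neurons, n_neurons))
    j = g.T @ g
    j = (j + j.T) / 2
    np.fill_diagonal(j, 0.0)
    return j
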