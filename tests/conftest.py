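import numpy as np
import pytest

from popcode import DecoderParams, EncoderParams, IsingParams, PatternTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240710)


def random_encoder(rng, n):
    return EncoderParams(
        amplitudes=rng.uniform(0.5, 2.0, n),
        centers=rng.normal(0.0, 2.0, n),
        widths=rng.uniform(0.5, 2.0, n),
    )


def random_ising(rng, n, scale=0.5):
    j = rng.normal(0.0, scale, (n, n))
    j = (j + j.T) / 2
    np.fill_diagonal(j, 0.0)
    return IsingParams(rng.normal(0.0, 1.0, n), j)


def random_decoder(rng, n, family="gaussian", hidden=8):
    a1 = np.sqrt(6.0 / n)
    a2 = np.sqrt(6.0 / hidden)
    return DecoderParams(
        family=family,
        w1=rng.uniform(-a1, a1, (hidden, n)),
        b1=rng.normal(0.0, 0.3, hidden),
        w2=rng.uniform(-a2, a2, (2, hidden)),
        b2=rng.normal(0.0, 0.3, 2),
    )


def constant_decoder(n, family, mu, sigma2):
    """Decoder whose output ignores the pattern: every r maps to (mu, sigma2)."""
    hidden = 3
    return DecoderParams(
        family=family,
        w1=np.zeros((hidden, n)),
        b1=np.zeros(hidden),
        w2=np.zeros((2, hidden)),
        b2=np.array([mu, np.log(sigma2)]),
    )


@pytest.fixture
def tbl3():
    return PatternTable(3)
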