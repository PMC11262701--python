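"""Stimulus distributions pi(x).

Every experiment in the package draws scalar stimuli from one of four
families:

* ``gaussian`` -- N(mean, variance);
* ``lognormal`` -- LN(log_mean, log_variance), i.e. ln x ~ N(mu, sigma^2);
* ``gaussian_mixture`` -- a finite mixture of Gaussians;
* ``tabulated_spectrum`` -- a density proportional to an acoustic power
  spectrum S(f) = A / (f0^p + f^p), tabulated on a frequency grid and
  sampled by inverse-CDF interpolation.

Parameters named "variance" are variances, not standard deviations: the
shorthand N(0, 5) means a Gaussian with variance 5, and LN(1, 1) a
log-normal whose log has mean 1 and variance 1.

All log densities and entropies are in nats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, stats


class ConfigurationError(ValueError):
    """Raised for invalid distribution parameters."""


@dataclass(frozen=True)
class AcousticSpectrumParams:
    """Power-law acoustic spectrum S(f) = A / (f0^p + f^p).

    Defaults are the published fit to environmental sound recordings:
    A = 2.4e6, f0 = 1.52e3 Hz, p = 2.61.  The frequency range over which
    the normalized density is defined is configurable; the default
    [20 Hz, 20 kHz] covers the human audible band.
    """

    amplitude: float = 2.4e6
    corner_frequency: float = 1.52e3
    exponent: float = 2.61
    f_min: float = 20.0
    f_max: float = 2.0e4
    n_grid: int = 4096

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.corner_frequency <= 0 or self.exponent <= 0:
            raise ConfigurationError("spectrum parameters must be positive")
        if not self.f_min < self.f_max:
            raise ConfigurationError("degenerate frequency range")
        if self.n_grid < 8:
            raise ConfigurationError("grid too coarse")

    def power(self, f):
        """Spectral power S(f) (unnormalized)."""
        f = np.asarray(f, dtype=float)
        return self.amplitude / (self.corner_frequency**self.exponent + f**self.exponent)


@dataclass(frozen=True)
class StimulusDistribution:
    """A scalar stimulus distribution pi(x).

    Use the class methods (:meth:`gaussian`, :meth:`lognormal`,
    :meth:`gaussian_mixture`, :meth:`from_spectrum`) rather than the raw
    constructor.
    """

    family: str
    params: dict = field(default_factory=dict)

    # -- constructors -------------------------------------------------

    @classmethod
    def gaussian(cls, mean: float, variance: float) -> "StimulusDistribution":
        if variance <= 0:
            raise ConfigurationError("variance must be positive")
        return cls("gaussian", {"mean": float(mean), "variance": float(variance)})

    @classmethod
    def lognormal(cls, log_mean: float, log_variance: float) -> "StimulusDistribution":
        if log_variance <= 0:
            raise ConfigurationError("log-variance must be positive")
        return cls(
            "lognormal",
            {"log_mean": float(log_mean), "log_variance": float(log_variance)},
        )

    @classmethod
    def gaussian_mixture(cls, means, variances, weights) -> "StimulusDistribution":
        means = np.asarray(means, dtype=float)
        variances = np.asarray(variances, dtype=float)
        weights = np.asarray(weights, dtype=float)
        if not (means.shape == variances.shape == weights.shape):
            raise ConfigurationError("mixture parameter shapes differ")
        if np.any(variances <= 0):
            raise ConfigurationError("variances must be strictly positive")
        if np.any(weights < 0) or not np.isclose(weights.sum(), 1.0, atol=1e-9):
            raise ConfigurationError("weights must be nonnegative and sum to 1")
        return cls(
            "gaussian_mixture",
            {"means": means, "variances": variances, "weights": weights},
        )

    @classmethod
    def from_spectrum(cls, sp: AcousticSpectrumParams) -> "StimulusDistribution":
        """Normalize S(f) on [f_min, f_max] into a tabulated density."""
        grid = np.linspace(sp.f_min, sp.f_max, sp.n_grid)
        power = sp.power(grid)
        norm = integrate.trapezoid(power, grid)
        density = power / norm
        cdf = integrate.cumulative_trapezoid(density, grid, initial=0.0)
        cdf /= cdf[-1]
        return cls(
            "tabulated_spectrum",
            {"grid": grid, "density": density, "cdf": cdf, "spectrum": sp},
        )

    # -- support ------------------------------------------------------

    @property
    def support(self) -> tuple[float, float]:
        if self.family == "gaussian" or self.family == "gaussian_mixture":
            return (-np.inf, np.inf)
        if self.family == "lognormal":
            return (0.0, np.inf)
        grid = self.params["grid"]
        return (float(grid[0]), float(grid[-1]))

    def _scipy_frozen(self):
        p = self.params
        if self.family == "gaussian":
            return stats.norm(loc=p["mean"], scale=np.sqrt(p["variance"]))
        if self.family == "lognormal":
            return stats.lognorm(s=np.sqrt(p["log_variance"]), scale=np.exp(p["log_mean"]))
        raise ConfigurationError(f"no frozen form for family {self.family!r}")

    # -- sampling -----------------------------------------------------

    def sample(self, n: int, seed: int | np.random.Generator) -> np.ndarray:
        """Draw ``n`` i.i.d. stimuli; identical seed gives identical output."""
        if n < 1:
            raise ConfigurationError("n must be >= 1")
        rng = np.random.default_rng(seed)
        p = self.params
        if self.family in ("gaussian", "lognormal"):
            return self._scipy_frozen().rvs(size=n, random_state=rng)
        if self.family == "gaussian_mixture":
            comp = rng.choice(len(p["weights"]), size=n, p=p["weights"])
            return rng.normal(p["means"][comp], np.sqrt(p["variances"][comp]))
        if self.family == "tabulated_spectrum":
            u = rng.uniform(size=n)
            return np.interp(u, p["cdf"], p["grid"])
        raise ConfigurationError(f"unknown family {self.family!r}")

    # -- density ------------------------------------------------------

    def log_density(self, x) -> np.ndarray:
        """log pi(x) in nats; -inf outside the support (never raises)."""
        x = np.asarray(x, dtype=float)
        p = self.params
        if self.family in ("gaussian", "lognormal"):
            with np.errstate(divide="ignore"):
                return self._scipy_frozen().logpdf(x)
        if self.family == "gaussian_mixture":
            comp = stats.norm.logpdf(
                x[..., None], loc=p["means"], scale=np.sqrt(p["variances"])
            )
            from scipy.special import logsumexp

            return logsumexp(comp, axis=-1, b=p["weights"])
        if self.family == "tabulated_spectrum":
            lo, hi = self.support
            inside = (x >= lo) & (x <= hi)
            dens = np.interp(x, p["grid"], p["density"])
            out = np.full_like(x, -np.inf, dtype=float)
            with np.errstate(divide="ignore"):
                out[inside] = np.log(dens[inside])
            return out
        raise ConfigurationError(f"unknown family {self.family!r}")

    def density(self, x) -> np.ndarray:
        return np.exp(self.log_density(x))

    # -- moments and entropy ------------------------------------------

    def mean(self) -> float:
        p = self.params
        if self.family == "gaussian":
            return p["mean"]
        if self.family == "lognormal":
            return float(np.exp(p["log_mean"] + p["log_variance"] / 2))
        if self.family == "gaussian_mixture":
            return float(np.dot(p["weights"], p["means"]))
        grid, dens = p["grid"], p["density"]
        return float(integrate.trapezoid(grid * dens, grid))

    def variance(self) -> float:
        p = self.params
        if self.family == "gaussian":
            return p["variance"]
        if self.family == "lognormal":
            s2 = p["log_variance"]
            return float((np.exp(s2) - 1) * np.exp(2 * p["log_mean"] + s2))
        if self.family == "gaussian_mixture":
            m = self.mean()
            return float(
                np.dot(p["weights"], p["variances"] + (p["means"] - m) ** 2)
            )
        grid, dens = p["grid"], p["density"]
        m = self.mean()
        return float(integrate.trapezoid((grid - m) ** 2 * dens, grid))

    def entropy(self) -> float:
        """Differential entropy H(pi) in nats.

        Closed form for the Gaussian and log-normal families; numerical
        quadrature of -pi log pi for the mixture and tabulated families.
        """
        p = self.params
        if self.family == "gaussian":
            return float(0.5 * np.log(2 * np.pi * np.e * p["variance"]))
        if self.family == "lognormal":
            return float(
                p["log_mean"] + 0.5 * np.log(2 * np.pi * np.e * p["log_variance"])
            )
        if self.family == "gaussian_mixture":
            lo = float(np.min(p["means"] - 12 * np.sqrt(p["variances"])))
            hi = float(np.max(p["means"] + 12 * np.sqrt(p["variances"])))

            def nlogn(x):
                ld = self.log_density(np.asarray([x]))[0]
                d = np.exp(ld)
                return -d * ld if d > 0 else 0.0

            val, _ = integrate.quad(nlogn, lo, hi, limit=400)
            return float(val)
        grid, dens = p["grid"], p["density"]
        with np.errstate(divide="ignore", invalid="ignore"):
            integrand = np.where(dens > 0, -dens * np.log(dens), 0.0)
        return float(integrate.trapezoid(integrand, grid))


def sample_stimuli(dist: StimulusDistribution, n: int, seed: int) -> np.ndarray:
    """Functional alias for :meth:`StimulusDistribution.sample`."""
    return dist.sample(n, seed)


def spectrum_to_distribution(sp: AcousticSpectrumParams) -> StimulusDistribution:
    """Functional alias for :meth:`StimulusDistribution.from_spectrum`."""
    return StimulusDistribution.from_spectrum(sp)
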