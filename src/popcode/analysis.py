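"""Post-hoc analyses of trained encoding-decoding models.

Covers decoding error (MAP and posterior-sampling mean-squared error),
stimulus-resolved error curves, the density of tuning-curve centers via
kernel density estimation, power-law fits of density / width / error
against the stimulus probability, and the scale-factor fit used to
compare model RMSE against frequency-difference-limen measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .decoder import DecoderParams, decode, map_estimates
from .encoder import EncoderParams, PatternTable, pattern_log_probs


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class FitResult:
    """Least-squares power-law fit log y = A - gamma log pi(x).

    ``gamma`` is the exponent of the fitted relation y = e^A pi(x)^(-gamma):
    positive gamma means y decreases where stimuli are more probable (the
    convention for tuning widths gamma_w and errors gamma_e); a density
    exponent gamma_d in d = A_d pi^gamma_d corresponds to -gamma.
    ``reliable`` marks fits whose variance explained reaches the quoting
    threshold (default 0.7).
    """

    gamma: float
    log_amplitude: float
    r_squared: float
    region: tuple[float, float]
    kind: str = "error"
    r2_threshold: float = 0.7

    @property
    def reliable(self) -> bool:
        return self.r_squared >= self.r2_threshold

    @property
    def density_exponent(self) -> float:
        """Exponent gamma_d of d(x) = A_d pi(x)^gamma_d."""
        return -self.gamma


@dataclass(frozen=True)
class ScaleFit:
    """Least-squares scale factor between an error curve and reference data."""

    scale: float
    residual: float
    r_squared: float


# ---------------------------------------------------------------------------
# Mean-squared error
# ---------------------------------------------------------------------------


def _q_table(enc: EncoderParams, tbl: PatternTable, x: np.ndarray) -> np.ndarray:
    return np.exp(pattern_log_probs(enc, x, tbl))


def mse_map(enc, dec: DecoderParams = None, tbl: PatternTable = None, stimuli=None):
    """MAP mean-squared error <sum_r q(r|x) (xhat(r) - x)^2>.

    Accepts either the raw triple (enc, dec, tbl, stimuli) or a
    :class:`~popcode.training.TrainedModel` as first argument with
    ``stimuli`` in original units (given either positionally in ``dec``
    or as the keyword).
    """
    from .training import TrainedModel

    if isinstance(enc, TrainedModel):
        model = enc
        stimuli = dec if stimuli is None else stimuli
        z = model.transform.forward(stimuli)
        tbl = model.pattern_table()
        raw = mse_map(model.encoder, model.decoder, tbl, z)
        return raw * model.transform.scale**2
    stimuli = np.atleast_1d(np.asarray(stimuli, dtype=float))
    if stimuli.size == 0:
        raise ValueError("stimulus batch must be nonempty")
    q = _q_table(enc, tbl, stimuli)
    xhat = map_estimates(dec, tbl)
    return float(np.mean(np.sum(q * (xhat - stimuli[:, None]) ** 2, axis=1)))


def mse_map_curve(enc, dec=None, tbl=None, grid=None) -> np.ndarray:
    """Per-stimulus error curve eps^2(x) on a grid (no outer average)."""
    from .training import TrainedModel

    if isinstance(enc, TrainedModel):
        model = enc
        grid = dec if grid is None else grid
        z = model.transform.forward(grid)
        curve = mse_map_curve(model.encoder, model.decoder, model.pattern_table(), z)
        return curve * model.transform.scale**2
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    q = _q_table(enc, tbl, grid)
    xhat = map_estimates(dec, tbl)
    return np.sum(q * (xhat - grid[:, None]) ** 2, axis=1)


def mse_sampling(enc, dec=None, prior=None, tbl=None, stimuli=None):
    """Mean-squared error when the estimate is a posterior sample.

    For the Gaussian decoder this is exactly mse_map + <sum_r q sigma^2(r)>;
    for the log-normal decoder the second moment of the log-normal gives an
    equally exact closed form.  Also accepts a TrainedModel as first
    argument (then the second positional argument is the stimuli).
    """
    from .training import TrainedModel

    if isinstance(enc, TrainedModel):
        model = enc
        stimuli = dec if stimuli is None else stimuli
        z = model.transform.forward(stimuli)
        raw = mse_sampling(
            model.encoder, model.decoder, model.prior, model.pattern_table(), z
        )
        return raw * model.transform.scale**2
    stimuli = np.atleast_1d(np.asarray(stimuli, dtype=float))
    q = _q_table(enc, tbl, stimuli)
    mu, sigma2 = decode(dec, tbl)
    if dec.family == "gaussian":
        second = np.sum(q * sigma2, axis=1)
        return mse_map(enc, dec, tbl, stimuli) + float(np.mean(second))
    # E[(xhat - x)^2], xhat ~ LN(mu, sigma^2)
    m1 = np.exp(mu + sigma2 / 2)
    m2 = np.exp(2 * mu + 2 * sigma2)
    err2 = m2 - 2 * stimuli[:, None] * m1 + stimuli[:, None] ** 2
    return float(np.mean(np.sum(q * err2, axis=1)))


# ---------------------------------------------------------------------------
# Neural density
# ---------------------------------------------------------------------------


def neural_density(enc, grid, bw_method=None) -> np.ndarray:
    """Gaussian-kernel density of the tuning-curve centers on a grid.

    ``enc`` is an :class:`EncoderParams`, a trained model, or a plain
    array of centers (e.g. pooled across seeds).  Bandwidth defaults to
    the Scott rule on the pooled centers.
    """
    from .training import TrainedModel

    if isinstance(enc, TrainedModel):
        centers = enc.centers
    elif isinstance(enc, EncoderParams):
        centers = enc.centers
    else:
        centers = np.asarray(enc, dtype=float)
    if centers.size < 2:
        raise ValueError("need at least two centers for a density estimate")
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    if np.ptp(centers) == 0:
        # degenerate population: a single narrow kernel at the shared center
        bw = 0.05 * (1 + abs(centers[0]))
        return stats.norm.pdf(grid, loc=centers[0], scale=bw)
    kde = stats.gaussian_kde(centers, bw_method=bw_method)
    return kde(grid)


# ---------------------------------------------------------------------------
# Power-law fits
# ---------------------------------------------------------------------------


def performance_region(grid, mse_curve, variance) -> tuple[float, float]:
    """Stimulus interval where the error beats the trivial variance bound.

    Returns the [min, max] of grid points with eps^2(x) < Var(pi); this
    is the default fitting region for the power-law analyses.
    """
    grid = np.asarray(grid, dtype=float)
    ok = np.asarray(mse_curve) < variance
    if not np.any(ok):
        raise FitError("error exceeds the stimulus variance everywhere")
    return float(grid[ok].min()), float(grid[ok].max())


def power_law_fit(xs, ys, dist, region=None, kind: str = "error") -> FitResult:
    """Fit log y = A - gamma log pi(x) by least squares within a region."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    log_pi = dist.log_density(xs)
    mask = np.isfinite(log_pi) & (ys > 0)
    if region is not None:
        mask &= (xs >= region[0]) & (xs <= region[1])
    else:
        region = (float(np.min(xs)), float(np.max(xs)))
    if mask.sum() < 3:
        raise FitError("fewer than 3 usable points in the fitting region")
    lx = log_pi[mask]
    ly = np.log(ys[mask])
    if np.allclose(ly, ly[0]):
        return FitResult(0.0, float(ly[0]), 0.0, region, kind)
    if np.allclose(lx, lx[0]):
        raise FitError("stimulus probability is constant over the region")
    res = stats.linregress(lx, ly)
    return FitResult(
        gamma=float(-res.slope),
        log_amplitude=float(res.intercept),
        r_squared=float(res.rvalue**2),
        region=region,
        kind=kind,
    )


def fit_rmse_scale(limens, rmse_curve) -> ScaleFit:
    """Scale factor a minimizing sum_f (log y(f) - log(eps(f)/a))^2.

    Closed form: log a = mean(log eps - log y).  ``limens`` is the
    reference column y(f) and ``rmse_curve`` the model eps(f), aligned on
    the same frequencies.  Both must be strictly positive.
    """
    y = np.asarray(limens, dtype=float)
    eps = np.asarray(rmse_curve, dtype=float)
    if y.shape != eps.shape:
        raise ValueError("mismatched table lengths")
    if np.any(y <= 0) or np.any(eps <= 0):
        raise ValueError("limens and RMSE must be strictly positive")
    log_a = float(np.mean(np.log(eps) - np.log(y)))
    resid = np.log(y) - (np.log(eps) - log_a)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((np.log(y) - np.mean(np.log(y))) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    return ScaleFit(scale=float(np.exp(log_a)), residual=ss_res, r_squared=r2)


def synthetic_limens(frequencies=None) -> tuple[np.ndarray, np.ndarray]:
    """SYNTHETIC stand-in for frequency-difference-limen measurements.

    Real limen datasets are not redistributed here; this generates a
    plausible two-column table (frequency in Hz, limen in Hz) following
    the well-known shape of human frequency discrimination: roughly
    constant (a few Hz) below ~500 Hz, then growing faster than linearly
    with frequency.  Use only for exercising the scale-fit machinery.
    """
    if frequencies is None:
        frequencies = np.array([125.0, 250.0, 500.0, 1000.0, 2000.0, 4000.0, 8000.0])
    f = np.asarray(frequencies, dtype=float)
    limen = 1.5 + 2.0e-3 * f * (f / 1000.0) ** 0.5
    return f, limen
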