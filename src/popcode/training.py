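"""Two-timescale constrained training of the encoder-decoder pair.

The constrained problem  min D  subject to  R <= Rbar  is solved through
its Lagrangian L = D + beta (R - Rbar): minibatch Adam descent on all
model parameters at the fast timescale, and one projected dual-ascent
step on the multiplier per epoch at the slow timescale,

    beta <- max(beta + eta_beta * (R - Rbar), 0),   beta(0) = 1.

Because every expectation over activity patterns is an exact enumerated
sum, the loss is a smooth closed-form function of all parameters, and its
gradients are derived analytically here (no stochastic gradient
estimator for the discrete latent is needed).  Positivity-constrained
quantities (amplitudes, widths) are optimized in log space.

Stimuli are standardized internally before training (affine for the
Gaussian decoder, multiplicative for the log-normal decoder) so that the
fixed Adam learning rate works across stimulus scales from O(1) to
acoustic frequencies in Hz; rates and stimulus-generative KL divergences
are invariant under this change of variables, and distortions are
reported in original stimulus units by adding back the log-Jacobian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit

from .decoder import DecoderParams, _S_CLIP
from .encoder import EncoderParams, PatternTable
from .ising import IsingParams, wishart_couplings
from .stimuli import StimulusDistribution


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite; carries a diagnostic parameter snapshot."""

    def __init__(self, message: str, snapshot: dict):
        super().__init__(message)
        self.snapshot = snapshot


@dataclass
class TrainingConfig:
    """Full specification of one training run.

    Defaults follow the reference recipe: 2000 training samples in
    minibatches of 128, Adam with learning rate 1e-4, dual-ascent step
    0.1 on the multiplier, at most 5000 epochs with early stopping when
    an exponential moving average of the training loss changes by less
    than 1e-5 for 100 consecutive epochs.
    """

    n_neurons: int = 12
    decoder_family: str = "gaussian"
    prior_kind: str = "ising"  # "ising" | "independent"
    target_rate: float = 1.0  # nats
    n_train: int = 2000
    n_test: int = 2000
    batch_size: int = 128
    learning_rate: float = 1e-4
    beta_lr: float = 0.1
    max_epochs: int = 5000
    tolerance: float = 1e-5
    patience: int = 100
    ema_factor: float = 0.9
    seed: int = 0
    hidden_width: int = 100
    nonlinearity: str = "tanh"
    init_noise: float = 0.01
    standardize: bool = True
    sigma2_floor: float = 1e-6
    map_mode: str = "standard"
    precision: str = "single"  # "single" | "double" batch arithmetic

    def __post_init__(self) -> None:
        if self.decoder_family not in ("gaussian", "lognormal"):
            raise ValueError(f"unknown decoder family {self.decoder_family!r}")
        if self.precision not in ("single", "double"):
            raise ValueError(f"unknown precision {self.precision!r}")
        if self.prior_kind not in ("ising", "independent"):
            raise ValueError(f"unknown prior kind {self.prior_kind!r}")
        if self.target_rate < 0:
            raise ValueError("target rate must be nonnegative")


# ---------------------------------------------------------------------------
# Unconstrained parameter vector and analytic gradients
# ---------------------------------------------------------------------------


def _fused_batch_numpy(logq, q, logp, mu, sigma2, target, lognormal, beta):
    """Batch x pattern inner computation (reference NumPy implementation).

    ``q`` is exp(logq), computed by the caller.  Returns
    (D, R, G, gsum, qbar, dmu, dsigma2) where G is the encoder backprop
    weight matrix q * (-ll + beta (log q - log p)) / B, gsum its row
    sums, qbar the batch-average pattern marginal and dmu/dsigma2 the
    accumulated distortion gradients w.r.t. each pattern's decoded mean
    and variance.
    """
    B = logq.shape[0]
    t = target[:, None] - mu
    inv = 1.0 / sigma2
    ll = -0.5 * t**2 * inv - 0.5 * np.log(2 * np.pi * sigma2)
    if lognormal:
        ll = ll - target[:, None]
    d = float(-np.mean(np.sum(q * ll, axis=1)))
    r = float(np.mean(np.sum(q * (logq - logp), axis=1)))
    g = q * (-ll + beta * (logq - logp)) / B
    gsum = g.sum(axis=1)
    qbar = q.mean(axis=0)
    d_ll = -q / B
    dmu = np.sum(d_ll * t, axis=0) * inv
    dsig = np.sum(d_ll * (0.5 * t**2 * inv - 0.5), axis=0) * inv
    return d, r, g, gsum, qbar, dmu, dsig


try:  # fused numba kernel: same arithmetic, no large temporaries
    from numba import njit

    @njit(cache=True, fastmath=True)
    def _fused_batch_numba(logq, q, logp, mu, sigma2, target, lognormal, beta):
        # patterns with q(r|x) < ~1e-15 contribute below double rounding
        # error to every accumulated quantity and are skipped
        B, P = logq.shape
        G = np.zeros_like(logq)
        gsum = np.zeros(B)
        qbar = np.zeros(P)
        dmu = np.zeros(P)
        dsig = np.zeros(P)
        log_term = 0.5 * np.log(2.0 * np.pi * sigma2)
        inv = 1.0 / sigma2
        d_acc = 0.0
        r_acc = 0.0
        for m in range(B):
            tm = target[m]
            srow = 0.0
            for k in range(P):
                lq = logq[m, k]
                qmk = q[m, k]
                if qmk < 1e-15:
                    continue
                t = tm - mu[k]
                ll = -0.5 * t * t * inv[k] - log_term[k]
                if lognormal:
                    ll -= tm
                d_acc -= qmk * ll
                r_acc += qmk * (lq - logp[k])
                g = qmk * (-ll + beta * (lq - logp[k])) / B
                G[m, k] = g
                srow += g
                qbar[k] += qmk / B
                dll = -qmk / B
                dmu[k] += dll * t * inv[k]
                dsig[k] += dll * (0.5 * t * t * inv[k] - 0.5) * inv[k]
            gsum[m] = srow
        return d_acc / B, r_acc / B, G, gsum, qbar, dmu, dsig

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False


def _params_to_modules(p: dict, cfg: TrainingConfig):
    """View the flat parameter dict as the three model components."""
    n = cfg.n_neurons
    enc = EncoderParams(
        amplitudes=np.exp(p["log_amp"]),
        centers=p["centers"].copy(),
        widths=np.exp(p["log_width"]),
    )
    j = np.zeros((n, n))
    if cfg.prior_kind == "ising":
        iu = np.triu_indices(n, k=1)
        j[iu] = p["j_upper"]
        j = j + j.T
    prior = IsingParams(
        p["h"].copy(), j, independent=(cfg.prior_kind == "independent")
    )
    dec = DecoderParams(
        family=cfg.decoder_family,
        w1=p["w1"].copy(),
        b1=p["b1"].copy(),
        w2=p["w2"].copy(),
        b2=p["b2"].copy(),
        nonlinearity=cfg.nonlinearity,
        sigma2_floor=cfg.sigma2_floor,
        map_mode=cfg.map_mode,
    )
    return enc, prior, dec


def loss_and_grads(
    p: dict,
    x: np.ndarray,
    tbl: PatternTable,
    beta: float,
    cfg: TrainingConfig,
    compute_grads: bool = True,
):
    """Exact L_beta = D + beta R on a batch, with analytic gradients.

    All pattern expectations are exact sums over the 2^N enumerated
    patterns; the batch dimension is an empirical average.  Returns
    (D, R, grads) with grads keyed like the parameter dict.
    """
    patterns = tbl.patterns  # (P, N)
    B = x.size
    # single precision halves the memory traffic of the batch-by-pattern
    # stage; all reductions still accumulate in double
    dtype = np.float32 if cfg.precision == "single" else np.float64
    pat = tbl.patterns_f32 if dtype is np.float32 else patterns

    # encoder forward
    w = np.exp(p["log_width"])
    w2 = w**2
    dxc = x[:, None] - p["centers"]  # (B, N)
    eta = p["log_amp"] - dxc**2 / (2 * w2)
    sp = expit(eta)
    log_norm = np.sum(-log_expit(-eta), axis=1)  # softplus sum
    log_q = eta.astype(dtype) @ pat.T - log_norm.astype(dtype)[:, None]  # (B, P)

    # prior forward
    energy = patterns @ p["h"]
    if cfg.prior_kind == "ising":
        n = cfg.n_neurons
        iu = np.triu_indices(n, k=1)
        j = np.zeros((n, n))
        j[iu] = p["j_upper"]
        j = j + j.T
        energy += np.sum((patterns @ j) * patterns, axis=1)
    e_max = energy.max()
    log_z = e_max + np.log(np.sum(np.exp(energy - e_max)))
    log_prior = energy - log_z
    prior_probs = np.exp(log_prior)

    # decoder forward
    w1c, b1c = p["w1"].astype(dtype), p["b1"].astype(dtype)
    w2c, b2c = p["w2"].astype(dtype), p["b2"].astype(dtype)
    pre = pat @ w1c.T + b1c  # (P, H)
    hidden = np.tanh(pre) if cfg.nonlinearity == "tanh" else np.maximum(pre, 0.0)
    out = hidden @ w2c.T + b2c  # (P, 2)
    mu = np.ascontiguousarray(out[:, 0])
    s = np.clip(out[:, 1], -_S_CLIP, _S_CLIP)
    es = np.exp(s)
    sigma2 = es + dtype(cfg.sigma2_floor)

    lognormal = cfg.decoder_family == "lognormal"
    target = np.log(x) if lognormal else x
    fused = _fused_batch_numba if _HAVE_NUMBA else _fused_batch_numpy
    q = np.exp(log_q)
    distortion, rate_val, g, gsum, qbar, d_mu, d_sigma2 = fused(
        log_q, q, log_prior.astype(dtype), mu, sigma2, target.astype(dtype),
        lognormal, beta,
    )
    if not compute_grads:
        return distortion, rate_val, None

    # ----- backward -----
    grads: dict[str, np.ndarray] = {}

    # encoder: dL/d eta via the score of the product-Bernoulli pattern law
    d_eta = g @ pat - sp * gsum[:, None]
    grads["log_amp"] = d_eta.sum(axis=0)
    grads["centers"] = np.sum(d_eta * dxc / w2, axis=0)
    grads["log_width"] = np.sum(d_eta * dxc**2 / w2, axis=0)

    # prior: only through beta * rate
    d_energy = -beta * (qbar - prior_probs)
    grads["h"] = patterns.T @ d_energy
    if cfg.prior_kind == "ising":
        dj_full = patterns.T @ (d_energy[:, None] * patterns)
        grads["j_upper"] = 2.0 * dj_full[iu]

    # decoder: only through the distortion
    d_s = d_sigma2 * es
    d_out = np.stack([d_mu, d_s], axis=1).astype(dtype)  # (P, 2)
    grads["w2"] = d_out.T @ hidden
    grads["b2"] = d_out.sum(axis=0, dtype=np.float64)
    d_hidden = d_out @ w2c
    if cfg.nonlinearity == "tanh":
        d_pre = d_hidden * (1.0 - hidden**2)
    else:
        d_pre = d_hidden * (pre > 0)
    grads["w1"] = d_pre.T @ pat
    grads["b1"] = d_pre.sum(axis=0, dtype=np.float64)

    return distortion, rate_val, grads


class Adam:
    """Adaptive moment estimation with standard hyperparameters."""

    def __init__(self, params: dict, lr: float, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        c1 = 1 - self.b1**self.t
        c2 = 1 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            params[k] -= self.lr * (self.m[k] / c1) / (
                np.sqrt(self.v[k] / c2) + self.eps
            )


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------


def _kmeans_centers(x: np.ndarray, k: int, seed: int) -> np.ndarray:
    from sklearn.cluster import KMeans

    if np.unique(x).size < k:
        warnings.warn(
            "fewer distinct stimuli than neurons; using quantile-spaced centers"
        )
        return np.quantile(x, (np.arange(k) + 0.5) / k)
    km = KMeans(n_clusters=k, n_init=4, random_state=seed).fit(x[:, None])
    return np.sort(km.cluster_centers_.ravel())


def initialize_parameters(
    cfg: TrainingConfig, stimuli: np.ndarray, seed
) -> dict:
    """Data-dependent initialization in the unconstrained parametrization.

    Centers are k-means centroids of the training stimuli (k = N), each
    width the distance to the nearest other center, amplitudes 1 (peak
    spiking probability 0.5); small Gaussian jitter is applied to the
    encoder parameters.  Prior biases start at 1 and couplings from the
    Wishart-style random construction; decoder weights are
    Kaiming-uniform with zero biases.
    """
    stimuli = np.asarray(stimuli, dtype=float)
    if stimuli.size == 0:
        raise ValueError("stimuli must be nonempty")
    if not isinstance(seed, np.random.SeedSequence):
        seed = np.random.SeedSequence(seed)
    s_km, s_jit, s_wis, s_dec = [
        s.generate_state(1)[0] % (2**31) for s in seed.spawn(4)
    ]

    n = cfg.n_neurons
    centers = _kmeans_centers(stimuli, n, int(s_km))
    if n == 1:
        widths = np.array([max(stimuli.std(), 1e-3)])
    else:
        dist = np.abs(centers[:, None] - centers[None, :])
        np.fill_diagonal(dist, np.inf)
        widths = dist.min(axis=1)
    widths = np.maximum(widths, 1e-3 * max(stimuli.std(), 1e-12))

    rng = np.random.default_rng(int(s_jit))
    jitter = lambda shape: rng.normal(scale=cfg.init_noise, size=shape)

    p = {
        "log_amp": np.zeros(n) + jitter(n),
        "centers": centers + jitter(n),
        "log_width": np.log(widths) + jitter(n),
        "h": np.ones(n),
    }
    if cfg.prior_kind == "ising":
        iu = np.triu_indices(n, k=1)
        p["j_upper"] = wishart_couplings(n, int(s_wis))[iu]
    dec = DecoderParams.initialize(
        cfg.decoder_family,
        n_inputs=n,
        hidden_width=cfg.hidden_width,
        nonlinearity=cfg.nonlinearity,
        seed=int(s_dec),
    )
    p.update({"w1": dec.w1, "b1": dec.b1, "w2": dec.w2, "b2": dec.b2})
    return p


# ---------------------------------------------------------------------------
# Stimulus standardization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StimulusTransform:
    """Invertible map between stimulus units and the internal training scale.

    ``affine``: z = (x - offset) / scale (Gaussian decoder);
    ``multiplicative``: z = x / scale (log-normal decoder, preserves
    positivity).  log |dz/dx| = -log scale in both cases.
    """

    kind: str = "identity"
    offset: float = 0.0
    scale: float = 1.0

    def forward(self, x):
        x = np.asarray(x, dtype=float)
        if self.kind == "affine":
            return (x - self.offset) / self.scale
        if self.kind == "multiplicative":
            return x / self.scale
        return x

    def inverse(self, z):
        z = np.asarray(z, dtype=float)
        if self.kind == "affine":
            return self.offset + self.scale * z
        if self.kind == "multiplicative":
            return self.scale * z
        return z

    @property
    def log_jacobian(self) -> float:
        """log dz/dx (constant); densities transform by +log_jacobian."""
        return 0.0 if self.kind == "identity" else -float(np.log(self.scale))

    @classmethod
    def fit(cls, x: np.ndarray, decoder_family: str) -> "StimulusTransform":
        if decoder_family == "lognormal":
            return cls("multiplicative", 0.0, float(np.exp(np.mean(np.log(x)))))
        return cls("affine", float(np.mean(x)), float(np.std(x)))


# ---------------------------------------------------------------------------
# Trained model container
# ---------------------------------------------------------------------------


@dataclass
class TrainedModel:
    """A trained encoder / prior / decoder triple.

    Component parameters live on the internal (standardized) stimulus
    scale; the attached :class:`StimulusTransform` maps to and from
    original units, and the convenience methods below report quantities
    in original units.
    """

    config: TrainingConfig
    encoder: EncoderParams
    prior: IsingParams
    decoder: DecoderParams
    transform: StimulusTransform
    beta: float
    history: pd.DataFrame
    stopped_epoch: int

    def pattern_table(self) -> PatternTable:
        return PatternTable(self.config.n_neurons)

    # -- encoder in stimulus units ------------------------------------

    @property
    def centers(self) -> np.ndarray:
        return self.transform.inverse(self.encoder.centers)

    @property
    def widths(self) -> np.ndarray:
        return self.encoder.widths * self.transform.scale

    @property
    def amplitudes(self) -> np.ndarray:
        return self.encoder.amplitudes

    def encoder_in_stimulus_units(self) -> EncoderParams:
        return EncoderParams(self.amplitudes.copy(), self.centers, self.widths)

    # -- densities and objectives in stimulus units --------------------

    def generative_log_density(self, x) -> np.ndarray:
        """log p(x) of the generative mixture, in original units."""
        from .decoder import generative_marginal_log_density

        z = self.transform.forward(x)
        tbl = self.pattern_table()
        return (
            generative_marginal_log_density(self.decoder, self.prior, tbl, z)
            + self.transform.log_jacobian
        )

    def evaluate(self, stimuli) -> "ObjectiveReport":
        from .objective import distortion, mutual_information, rate

        tbl = self.pattern_table()
        z = self.transform.forward(stimuli)
        d = distortion(self.encoder, self.decoder, tbl, z) - self.transform.log_jacobian
        r = rate(self.encoder, self.prior, tbl, z)
        mi = mutual_information(self.encoder, tbl, z)
        return ObjectiveReport(
            distortion=d, rate=r, mutual_information=mi, beta=self.beta,
            target_rate=self.config.target_rate,
        )

    def kl_from_stimulus(self, dist, n_mc: int, seed) -> tuple[float, float]:
        """MC estimate (value, SE) of KL(pi || p_psi(x)) in nats."""
        from .objective import kl_stimulus_generative

        tbl = self.pattern_table()
        return kl_stimulus_generative(
            dist, self.decoder, self.prior, tbl, n_mc, seed,
            model_log_density=self.generative_log_density,
        )


@dataclass
class ObjectiveReport:
    distortion: float
    rate: float
    mutual_information: float
    beta: float
    target_rate: float

    @property
    def neg_elbo(self) -> float:
        return self.distortion + self.rate


# ---------------------------------------------------------------------------
# Main training loop (Algorithm: two-timescale gradient descent-ascent)
# ---------------------------------------------------------------------------


def train(
    cfg: TrainingConfig,
    dist: StimulusDistribution,
    stimuli: np.ndarray | None = None,
    log_path=None,
) -> TrainedModel:
    """Run the two-timescale constrained optimization.

    ``stimuli`` overrides the training set (otherwise ``cfg.n_train``
    fresh samples are drawn from ``dist`` under ``cfg.seed``).  Returns
    the trained model with its per-epoch history (epoch, D, R, -ELBO,
    beta); the history is also appended to ``log_path`` as CSV when
    given.  Identical configuration and seed give identical results.
    """
    ss = np.random.SeedSequence(cfg.seed)
    s_data, s_init, s_shuffle = ss.spawn(3)
    if stimuli is None:
        stimuli = dist.sample(cfg.n_train, np.random.default_rng(s_data))
    stimuli = np.asarray(stimuli, dtype=float)

    transform = (
        StimulusTransform.fit(stimuli, cfg.decoder_family)
        if cfg.standardize
        else StimulusTransform()
    )
    z = transform.forward(stimuli)

    tbl = PatternTable(cfg.n_neurons)
    params = initialize_parameters(cfg, z, s_init)
    opt = Adam(params, lr=cfg.learning_rate)
    rng = np.random.default_rng(s_shuffle)

    beta = 1.0
    ema = None
    streak = 0
    rows = []
    n_batches = max(1, int(np.ceil(z.size / cfg.batch_size)))

    epoch = 0
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(z.size)
        d_sum = r_sum = 0.0
        for b in range(n_batches):
            idx = order[b * cfg.batch_size : (b + 1) * cfg.batch_size]
            if idx.size == 0:
                continue
            d, r, grads = loss_and_grads(params, z[idx], tbl, beta, cfg)
            if not np.isfinite(d + r):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch} (D={d}, R={r})",
                    snapshot={k: v.copy() for k, v in params.items()},
                )
            opt.step(params, grads)
            d_sum += d * idx.size
            r_sum += r * idx.size
        d_epoch = d_sum / z.size
        r_epoch = r_sum / z.size

        loss = d_epoch + beta * r_epoch
        rows.append(
            {
                "epoch": epoch,
                "distortion": d_epoch,
                "rate": r_epoch,
                "neg_elbo": d_epoch + r_epoch,
                "beta": beta,
            }
        )

        # slow timescale: projected dual ascent on the multiplier
        beta = max(beta + cfg.beta_lr * (r_epoch - cfg.target_rate), 0.0)

        # early stopping on an EMA of the training loss
        new_ema = loss if ema is None else cfg.ema_factor * ema + (1 - cfg.ema_factor) * loss
        if ema is not None and abs(new_ema - ema) < cfg.tolerance:
            streak += 1
        else:
            streak = 0
        ema = new_ema
        if streak >= cfg.patience:
            break

    history = pd.DataFrame(rows)
    if log_path is not None:
        history.to_csv(log_path, index=False)

    enc, prior, dec = _params_to_modules(params, cfg)
    return TrainedModel(
        config=cfg,
        encoder=enc,
        prior=prior,
        decoder=dec,
        transform=transform,
        beta=beta,
        history=history,
        stopped_epoch=epoch,
    )


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------


def rate_distortion_sweep(
    cfg: TrainingConfig,
    dist: StimulusDistribution,
    target_rates,
    seeds,
    keep_models: bool = False,
):
    """Train one model per (target rate, seed) and tabulate the frontier.

    Returns (DataFrame, models) where the frame has one row per run with
    evaluation-set distortion, rate, -ELBO, final beta, KL(pi || p(x)),
    MAP and sampling MSE, prior entropy and tuning-curve summaries.
    Individual run failures are recorded (``failed`` column) and the
    sweep continues.
    """
    from .analysis import mse_map, mse_sampling
    from .ising import prior_entropy

    rows = []
    models: dict[tuple[float, int], TrainedModel] = {}
    for rbar in np.atleast_1d(target_rates):
        for seed in np.atleast_1d(seeds):
            run_cfg = replace(cfg, target_rate=float(rbar), seed=int(seed))
            row = {"target_rate": float(rbar), "seed": int(seed), "failed": False}
            try:
                model = train(run_cfg, dist)
                x_eval = dist.sample(
                    cfg.n_test, np.random.default_rng([int(seed), 915_001])
                )
                rep = model.evaluate(x_eval)
                kl, kl_se = model.kl_from_stimulus(
                    dist, cfg.n_test, np.random.default_rng([int(seed), 915_002])
                )
                tbl = model.pattern_table()
                row.update(
                    distortion=rep.distortion,
                    rate=rep.rate,
                    neg_elbo=rep.neg_elbo,
                    mutual_information=rep.mutual_information,
                    beta=model.beta,
                    kl=kl,
                    kl_se=kl_se,
                    mse_map=mse_map(model, x_eval),
                    mse_sampling=mse_sampling(model, x_eval),
                    prior_entropy=prior_entropy(model.prior, tbl),
                    mean_width=float(np.mean(model.widths)),
                    mean_amplitude=float(np.mean(model.amplitudes)),
                    epochs=model.stopped_epoch,
                )
                if keep_models:
                    models[(float(rbar), int(seed))] = model
            except TrainingDivergedError as err:
                row["failed"] = True
                row["error"] = str(err)
            rows.append(row)
    return pd.DataFrame(rows), models


def generalization_experiment(
    cfg: TrainingConfig,
    dist: StimulusDistribution,
    train_sizes,
    target_rates,
    seeds,
) -> pd.DataFrame:
    """Train/test metrics as a function of training-set size.

    The minibatch size is scaled in proportion to the training-set size
    (relative to the 2000/128 reference) so the number of gradient steps
    per epoch stays comparable.  The generalization gap is
    D_test - D_train; the rate is reported for both splits as well.
    """
    rows = []
    for n_train in np.atleast_1d(train_sizes):
        batch = max(2, int(round(cfg.batch_size * int(n_train) / 2000)))
        for rbar in np.atleast_1d(target_rates):
            for seed in np.atleast_1d(seeds):
                run_cfg = replace(
                    cfg,
                    n_train=int(n_train),
                    batch_size=batch,
                    target_rate=float(rbar),
                    seed=int(seed),
                )
                model = train(run_cfg, dist)
                x_trn = dist.sample(
                    int(n_train),
                    np.random.default_rng(np.random.SeedSequence(int(seed)).spawn(3)[0]),
                )
                x_tst = dist.sample(
                    cfg.n_test, np.random.default_rng([int(seed), 915_003])
                )
                rep_trn = model.evaluate(x_trn)
                rep_tst = model.evaluate(x_tst)
                rows.append(
                    {
                        "n_train": int(n_train),
                        "target_rate": float(rbar),
                        "seed": int(seed),
                        "distortion_train": rep_trn.distortion,
                        "distortion_test": rep_tst.distortion,
                        "rate_train": rep_trn.rate,
                        "rate_test": rep_tst.rate,
                        "gap": rep_tst.distortion - rep_trn.distortion,
                        "rate_gap": rep_tst.rate - rep_trn.rate,
                        "beta": model.beta,
                    }
                )
    return pd.DataFrame(rows)
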