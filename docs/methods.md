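# Methods

## Model

`popcode` implements a jointly optimized encoding-decoding model of a small
sensory population. A scalar stimulus x is drawn from a known environment
distribution pi(x) and encoded by N binary neurons ("spike" / "no spike" in a
short coding window). Neuron i spikes independently with probability
S(eta_i(x)), where S is the logistic function and

    eta_i(x) = ln A_i - (x - c_i)^2 / (2 w_i^2)

is a bell-shaped (Gaussian) tuning curve on the natural-parameter scale, with
amplitude A_i, preferred stimulus c_i and tuning width w_i. With A_i = 1 the
neuron spikes with probability 1/2 at its preferred stimulus. The population
response r is one of 2^N binary patterns.

The decoding side is a generative model: a maximum-entropy (Ising) prior over
patterns, p(r) = exp(h'r + r'Jr - ln Z), and a two-layer network that maps
each pattern to the mean and log-variance of a Gaussian or log-normal
conditional p(x|r). The generative marginal p(x) = sum_r p(x|r) p(r) is a
2^N-component mixture.

Encoder and generative model are trained to match the two joint distributions,
which is the variational-autoencoder objective: the negative evidence lower
bound decomposes into a distortion D (expected negative conditional
log-likelihood of the stimulus after encode-decode) and a rate R (expected KL
divergence between the stimulus-evoked pattern distribution and the prior).
Because flexible decoders admit degenerate low-rate optima (posterior
collapse), the package solves the constrained problem

    min D   subject to   R <= Rbar,

via the Lagrangian L = D + beta (R - Rbar) with a two-timescale scheme:
minibatch Adam on all parameters at the fast timescale and one projected
dual-ascent step per epoch on beta (initialized at 1, clamped at 0). When the
converged beta* is positive the constraint is active (R = Rbar), and where
beta* = 1 the solutions also maximize the ELBO and fall on the line
D = H(pi) - Rbar in the rate-distortion plane.

## Exact enumeration and analytic gradients

All expectations over patterns are exact sums over the enumerated 2^N
patterns (N is capped at 20; there is no MCMC or large-N approximation).
A consequence is that the training loss is a smooth closed-form function of
every parameter, so no stochastic estimator for discrete latent variables is
needed: the package ships hand-derived analytic gradients (verified against
central finite differences in the test suite at relative error < 1e-4, and
typically < 1e-6) and a hand-written Adam optimizer. The inner
batch-by-pattern computation has a reference NumPy implementation and an
equivalent fused numba kernel (tested to agree to 1e-12); the kernel is used
when numba is importable.

Positivity of amplitudes and widths is maintained by optimizing their
logarithms; the coupling matrix is parametrized by its strict upper triangle
and symmetrized, which preserves symmetry and the zero diagonal under
unconstrained updates.

## Stimulus distributions

Four families are built in, with parameters meaning (mean, variance) — i.e.
N(0, 5) has variance 5 and LN(1, 1) has log-mean 1 and log-variance 1:

* Gaussian, log-normal, and a three-component Gaussian mixture
  (defaults used in the multimodal experiments: means {-4, 0, 2}, variances
  {1, 0.5, 1}, weights {0.3, 0.2, 0.5});
* an acoustic-frequency distribution proportional to the power spectrum
  S(f) = A / (f0^p + f^p) with A = 2.4e6, f0 = 1.52e3 Hz, p = 2.61,
  normalized on a configurable band (default 20 Hz - 20 kHz, 4096 grid
  points; the band is a package choice — the source fit does not state one)
  and sampled by inverse-CDF interpolation on the grid.

These generators define the study conditions for every experiment; no
external data are required. The shipped frequency-difference-limen table is a
synthetic stand-in (clearly labelled as such) used only to exercise the
RMSE-scale fit; conclusions about real psychophysics require real limen data.

## Internal standardization

Training standardizes stimuli internally: affine z = (x - m)/s for the
Gaussian decoder, multiplicative z = x/s (s the geometric mean) for the
log-normal decoder, with statistics from the training set. This makes the
fixed Adam learning rate (1e-4) usable across stimulus scales from O(1) to
acoustic frequencies of order 10^4 Hz. The rate, the mutual information and
KL(pi || p(x)) are invariant under this common change of variables;
distortion and stimulus entropy shift by the same log-Jacobian constant and
are always reported consistently in original stimulus units; MSE scales by
s^2 and is likewise reported in original units. Setting ``standardize=False``
recovers raw-unit training. Acoustic frequencies are encoded in raw Hz by
default (a log transform can be emulated by passing log-frequencies).

## Hyperparameters and defaults

* n_train = 2000 samples, minibatch 128, Adam lr 1e-4 (standard moments),
  dual step eta_beta = 0.1, beta(0) = 1, at most 5000 epochs.
* Early stopping: exponential moving average of the epoch training loss with
  factor 0.9; stop when it changes by less than 1e-5 for 100 consecutive
  epochs. (The averaging window is a package choice; only the tolerance and
  patience are inherited.)
* Initialization: tuning centers are k-means centroids (k = N) of the
  training stimuli, widths the distance to the nearest other center,
  amplitudes 1; Gaussian jitter of sd 0.01 is added in the unconstrained
  parametrization. Prior biases start at 1; couplings from a Wishart-style
  construction (G'G with i.i.d. entries of variance 1/N, diagonal zeroed —
  one concrete reading of an under-specified recipe, flagged here).
  Decoder weights are Kaiming-uniform (+-sqrt(6/fan_in)), biases 0. If the
  stimuli have fewer distinct values than N, centers fall back to quantiles
  with a warning.
* Decoder: 100 tanh hidden units by default (the reference description says
  only "two-layer network"; width and nonlinearity are configurable), output
  log-variance exponentiated with a floor of 1e-6 on sigma^2.
* All information quantities are in nats.

## Numerical and design choices

* The decoded scale parameter is a *variance* (the network outputs
  log-variance); the conditional densities are the exact Gaussian /
  log-normal negative log-densities.
* Log-normal MAP estimate: the distribution mode exp(mu - sigma^2) by
  default; a `map_mode="literal"` switch selects exp(mu - 2 sigma^2), a
  variant that appears in some descriptions of this model. The discrepancy
  is surfaced rather than silently resolved.
* Fisher information of the Bernoulli encoder is the exact score variance
  J(x) = sum_j (x-c_j)^2 / w_j^4 * S(eta_j)(1 - S(eta_j)); it is verified
  against an enumeration oracle to 1e-8. The inverse Fisher information is
  *not* expected to predict the decoder MSE here (the decoder is not ideal
  and may be biased); the analysis code computes both but asserts no
  agreement.
* The sampling MSE is computed in closed form for both decoder families
  (for the log-normal decoder via its first two moments), and is verified
  against a Monte-Carlo oracle.
* Power-law fits log y = A - gamma log pi(x) are ordinary least squares in
  log-log space, restricted by default to the region where the MAP MSE is
  below the stimulus variance; exponents are flagged "reliable" only when
  R^2 >= 0.7. KDE of tuning centers uses a Gaussian kernel with Scott's
  bandwidth (bandwidth configurable; none is prescribed by the protocol).
  Multi-seed tuning summaries sort neurons by preferred stimulus before
  averaging; KDE pools centers across seeds.
* Rate-distortion sweeps and generalization runs are specified in nats; the
  minibatch size in generalization runs scales in proportion to the
  training-set size.

## Problem sizes

Exact enumeration makes the per-epoch cost scale as 2^N. The package's
experiment presets and test suite run at desk scale as a deliberate choice:
N = 12 for the grey-region and acoustic runs, N = 8-10 for trend and
generalization proxies, 2 - 4 random initializations instead of 16, and a
desk optimizer setting of lr = 3e-4 with about 2000 epochs. On the
grey-region reference condition (log-normal stimuli, N = 12, target rate
1.32) the desk setting reproduces the converged solution of the full recipe
(lr 1e-4, 5000 epochs) to within the run-to-run spread: D + R = 2.453 vs
2.457, achieved rate 1.336 vs 1.339, converged multiplier 1.005 vs 1.01, and
KL(pi || p(x)) 0.017 vs 0.016 nats. The resource-allocation
exponents (gamma_d about 0.5-0.6, gamma_w about 0.7, gamma_e about 0.6-0.9 in
the reference protocol) are stable only when averaged over 16 seeds at full
scale; at desk scale the package asserts the qualitative trends instead (the
density exponent and the density-width anticorrelation sharpen with the
target rate, and the error decreases with stimulus probability with a good
power-law fit).

## Known limitations

* Enumeration limits N to about 20 in principle and about 12-14 in practice.
* Conditional independence of neurons given the stimulus (no noise
  correlations), binary responses only.
* Scalar stimuli only; the acoustic case treats frequency as the single
  coded dimension.
* The two-timescale dual dynamics can oscillate before settling when the
  initial rate is far from the target; runs at very low targets converge to
  the collapsed regime instead of an active constraint (beta -> 0), which is
  the expected behavior of the constrained problem.
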