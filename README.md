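# popcode

Jointly optimized encoding and decoding in small neural populations.

`popcode` is for computational neuroscientists who want to study how a
population of sensory neurons should allocate its coding resources —
preferred stimuli, tuning widths, response amplitudes, and the structure of
spontaneous activity — when encoder and decoder are optimized *together*
rather than assuming an ideal Bayesian decoder.

## The model

A scalar stimulus x ~ pi(x) is encoded by N binary neurons that spike
independently with probability S(eta_i(x)), where
eta_i(x) = ln A_i − (x − c_i)² / (2 w_i²) is a Gaussian tuning curve on the
logit scale (S is the logistic function). The decoding side is a generative
model: an Ising prior p(r) = exp(hᵀr + rᵀJr − ln Z) over the 2^N activity
patterns, and a two-layer network mapping each pattern to the mean and
variance of a Gaussian or log-normal conditional p(x|r). Matching the
recognition and generative joint distributions is the variational-autoencoder
objective; its negative ELBO splits into a distortion D (reconstruction
penalty) and a rate R (KL between evoked activity and the prior — an abstract
metabolic cost). Because flexible decoders make the unconstrained optimum
degenerate (posterior collapse), `popcode` solves the constrained problem

    min D   subject to   R ≤ R̄

by two-timescale gradient descent-ascent on the Lagrangian D + β(R − R̄):
minibatch Adam on all parameters, one projected dual-ascent step on β per
epoch. Sweeping the target rate R̄ traces a family of solutions along the
optimal frontier D = H(pi) − R̄, from broad, noisy, overlapping tuning curves
(low rate) to narrow curves that tile the stimulus space (high rate). All
pattern sums are exact (2^N enumeration, N ≤ 20), so gradients are
closed-form and training needs no discrete-gradient estimator.

## A worked example

Train a 10-neuron model on a Gaussian stimulus distribution at a mid-range
target rate, and inspect the solution:

```python
import numpy as np
from popcode import StimulusDistribution, TrainingConfig, train

dist = StimulusDistribution.gaussian(0.0, 5.0)      # N(0, variance 5)
cfg = TrainingConfig(n_neurons=10, target_rate=1.5,  # nats
                     learning_rate=3e-4, max_epochs=2000, seed=0)
model = train(cfg, dist)

x = dist.sample(2000, seed=1)
rep = model.evaluate(x)
kl, se = model.kl_from_stimulus(dist, 2000, seed=2)
print(f"D = {rep.distortion:.3f}  R = {rep.rate:.3f}  "
      f"D+R = {rep.neg_elbo:.3f}  H(pi) = {dist.entropy():.3f}")
print(f"beta* = {model.beta:.2f}   KL(pi || p(x)) = {kl:.3f} +- {se:.3f}")
```

Output from this exact configuration:

```
D = 0.725  R = 1.527  D+R = 2.252  H(pi) = 2.224
beta* = 0.99   KL(pi || p(x)) = 0.003 +- 0.002
```

Read: the constraint is active (R ≈ R̄ = 1.5, β* ≈ 1), the negative ELBO
D + R sits on the theoretical optimum H(pi) − R̄ + R̄ = H(pi) to within about
one percent, and the generative marginal reproduces the stimulus distribution
(KL ≈ 0.003 nats). Raising R̄ lowers D (better reconstruction, narrower
tuning curves); lowering it toward 0 collapses the code (R → 0, broad
low-amplitude tuning curves) while the generative model stays accurate.

The same machinery is exposed on the command line:

```
popcode train --config run.yaml --out runs/demo
popcode sweep | generalize | analyze | preset   # see --help
```

Presets (`popcode preset fig4_sweep`, `fig9_acoustic`, ...) bundle the
standard experiment protocols: rate-distortion sweeps, generalization versus
training-set size, resource-allocation power-law fits, and the acoustic-
frequency case study built from the environmental power spectrum
S(f) = A/(f₀^p + f^p) (A = 2.4e6, f₀ = 1520 Hz, p = 2.61).

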