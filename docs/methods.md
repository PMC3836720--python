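# Methods

## The models

All four families share one observation model: a spike train binned at
width `dt` is a sequence of conditionally independent Bernoulli draws,

    P(y_t = 1 | x_t, s_t) = σ(f(x_t, s_t)),    σ(z) = 1 / (1 + e^{-z}),

where `x_t` is a stimulus feature vector (dimension D) and `s_t` a
spike-history vector (dimension H).  The families differ only in the
predictor `f`:

| family        | predictor                                                            |
|---------------|----------------------------------------------------------------------|
| linear (GLM)  | `w'x + h's + b`                                                      |
| quadratic     | `½ x'Ax + w'x + h's + b`                                             |
| STM           | `log Σ_k exp(½ x'A_k x + w_k'x + a_k) + h's`                         |
| factored STM  | `log Σ_k exp(Σ_m β_km (u_m'x)² + w_k'x + a_k) + h's`                 |

The STM arises from a generative view: if the stimulus features in
spiking bins follow a K-component Gaussian mixture and those in
non-spiking bins a single Gaussian, the exact Bayes posterior of a spike
is `σ(f)` with the STM's `f`.  The log-sum-exp is a *soft maximum* over
per-component quadratic responses, so the model can respond differently
in different regions of stimulus space.  With K = 1 the STM is exactly
the quadratic model, and with equal class covariances the quadratic term
vanishes and the GLM remains.  The factored variant shares low-rank
quadratic feature directions `u_m` across components, so its parameter
count `MD + KM + KD + K + H` grows linearly in D (e.g. 246 parameters at
D = 10, H = 100, K = 6, M = 5, against `K(D(D+1)/2 + D + 1) + H` for the
dense STM).

The history term is a naive-Bayes log-ratio of interspike-interval
distributions, `log g1(Δt) − log g0(Δt)`, where `g1`/`g0` are histograms
of the time since the last spike conditioned on the current bin
containing / not containing a spike.  Because `s_t` is one-hot at the
most recent spike's position (all-zero if none within the window), this
ratio is identical to a linear filter `h's_t`; the filter form is what
the optimizer sees.  The history filter is shared across mixture
components, and the factored STM carries no global bias (it is absorbed
into the per-component `a_k`; this is also what makes the parameter
count above come out).

Conventions: quadratic forms use `½ x'Ax` with `A` stored symmetric
(symmetrized on ingestion); `log_sum_exp` uses max-subtraction; history
index 0 is the *most recent* history bin (time increases with index into
the past).

## Estimation

**Generative initialization (STM).**  The spike-triggered mixture is
fitted by in-package EM with k-means++-style seeding, 5 restarts and a
relative tolerance of 1e-8 on the mean log-likelihood; covariances
receive diagonal jitter of 1e-6 × mean-diagonal whenever a Cholesky
factorization fails, escalating tenfold until it succeeds.  The
non-spike-triggered distribution is a single maximum-likelihood Gaussian
(1/N covariance normalization).  Closed-form Bayes conversion gives
`A_k = Σ0⁻¹ − Σ1k⁻¹`, `w_k = Σ1k⁻¹μ1k − Σ0⁻¹μ0`, with `a_k` collecting
log-weights, log-determinants, Mahalanobis constants and the prior
log-odds; the identity to the brute-force posterior is exact (no
sampling) and is asserted to 1e-8 in the tests.  ISI histograms use a
0.5 pseudo-count in every bin before normalization so empty bins give
finite filter values.  The prior log-odds are folded into `a_k` and are
free to move during fine-tuning (the alternative — freezing them — has
no representational consequence because of the model's additive
redundancy).

**Discriminative training.**  All families are fine-tuned by L-BFGS on
the mean Bernoulli negative log-likelihood with analytic gradients.  The
objective is optimized in nats and reported in bits (÷ log 2).  For the
STM families the gradient routes each bin's sigmoid residual
`σ(f_t) − y_t` to component k with softmax responsibility weights
`γ_tk`; correctness is verified against central finite differences
(step 1e-5, relative error < 1e-5) for every family.  Quadratic
matrices are optimized as full D×D blocks: the objective depends only on
the symmetric part, and the gradient is itself symmetric, so symmetric
initializations stay symmetric.  Probabilities entering explicit
log-likelihoods are clipped to [1e-12, 1−1e-12]; the sigmoid families
use the softplus form `log(1+e^f) − y f`, which needs no clipping.
Factored STMs start from random entries ~ N(0, 0.01) with component
biases at the empirical spike-rate logit.

**Early stopping.**  With a validation split, the validation objective
is evaluated every 5 optimizer iterations; after 50 consecutive checks
without a new minimum, training stops and the parameters at the best
checked iteration are returned.  Both cadence and patience are
`TrainConfig` fields.

**Multi-step linear/quadratic recipe.**  Stage 1 is the concave sigmoid
fit.  Stage 2 replaces the sigmoid with a sum of Gaussian blobs squashed
by tanh, `p(z) = tanh(Σ_i α_i exp(−(z−c_i)²/2s_i²))` with `α_i, s_i > 0`
via log-parametrization (output in [0, 1)), and alternates 10 rounds of
≤ 50 L-BFGS iterations over the filter and the nonlinearity; blobs start
on quantiles of the filter response with heights fitted by least squares
to track the sigmoid.  Because a sign-invariant (e.g. V-shaped) response
leaves the concave stage-1 filter at zero by symmetry, stage 2 also
tries a second candidate filter seeded from the leading eigenvector of
the spike-triggered covariance difference (classical STC
initialization) and keeps the better training fit.  Stage 3 maps the
nonlinearity nonparametrically with a 150-bin histogram of
P(spike | filter response) over the training range.  Each stage is kept
only if it does not degrade the monitoring objective (validation data if
provided, else training) by more than 1e-3 bits/bin, so the pipeline
never ends worse than its concave stage.

## Evaluation

Cross-entropy is the held-out mean of `−log₂ P(y_t | x_t, s_t)`
(bits/bin; ÷ dt for bits/s).  The stimulus-information rate is estimated
as `(CE_historyOnly − CE_full)/dt`, where the history-only model is the
same family with the stimulus terms dropped; the bound can be negative
for models worse than the history-only baseline, which is reported
as-is.

The PSTH oracle predicts trial r of a frozen-stimulus block as the
offset plus the Gaussian-kernel-smoothed mean of the other N−1 trials,
clipped at 1 − 1e-9 before the Bernoulli likelihood.  Kernels are
truncated at ±4σ with FWHM = σ·2√(2 ln 2) and renormalized by the local
kernel mass at the edges (a constant train smooths to the same
constant).  Kernel width and offset are chosen on a log-spaced grid
(FWHM 0.05–5 ms, offset 1e-4–1e-1 by default) by minimizing the mean
leave-one-out cross-entropy, ties broken toward the wider kernel and
then the larger offset.  The offset is added after smoothing, before
clipping.  Explained variance (R²) is the squared Pearson correlation of
two smoothed rate vectors — it inherits the kernel-width dependence of
the PSTHs, so R² values are only comparable at a fixed kernel.  Paired
model comparisons across cells use a one-tailed Wilcoxon signed-rank
test through the standard scipy routine.

## The simulator

The synthetic pipeline emulates a white-noise single-unit protocol:
Gaussian white noise low-pass filtered at 100 Hz (4th-order zero-phase
Butterworth), standardized to zero mean and unit variance; 10 ms
stimulus windows strictly preceding each bin, reduced to 10 principal
components (basis fitted on training windows only, no whitening); 25 ms
of spike history in 100 equal bins with all but the most recent spike
removed; 50 unfrozen plus 50 frozen trials by default.  The waveform is
sampled at 4 kHz and the spike train binned at 0.25 ms so one history
bin equals one spike bin and no bin can hold more than one spike; the
bin width is a package choice, made so the history encoding is exact.
Bins at the start of a trial without a full stimulus window are dropped
and counted.

Spike sampling is sequential: the history vector at bin t is rebuilt
from the spikes already sampled, so refractoriness and bursting feed
back into the simulation.  Ground-truth neurons draw filters scaled by
the feature standard deviations of a calibration stimulus (so every
family produces comparable drive), impose an exponentially decaying
refractory history filter, and calibrate their bias by bisection until
the simulated mean rate hits a 50 Hz target (2% tolerance, ≤ 100
steps) — within the 20–120 Hz range typical of the modelled
preparation.

What the simulator does *not* reproduce: correlated natural stimuli,
slow nonstationarity (adaptation drift, electrode instability), spike
sorting errors, and bursting structure beyond what the one-spike history
term can express.  Passing recovery tests therefore show correctness of
the estimation machinery under the model's own assumptions, not that
real cells are STMs.

## Study sizes and numerical choices

The simulation studies in the test suite and the acceptance script use
desk-scale sizes chosen as the package's own defaults: recovery and
model-ordering studies use K = 3 STM neurons with D = 5 features and
about 52,000 training bins (two 6.5 s unfrozen trials), evaluated on a
held-out frozen trial, over 10 seeds; learning curves fit factored STMs
(K = 3, M = 3) on 1k/5k/20k-bin subsets with a 50/50
optimization/validation split and early stopping; PSTH checks use 30
frozen trials of 4 s from a history-free neuron.  Model-cell PSTHs
default to 1000 sampled trains where a full PSTH comparison is wanted,
configurable downward.

Degenerate inputs have explicit policies: identical samples get a
jittered covariance rather than an error; empty ISI bins are floored by
the pseudo-count; an all-zero history row contributes zero to the
predictor; zero-variance rate vectors make R² an error rather than a
NaN.  Model files are a versioned `.npz` container with a family tag and
all arrays; loading a mismatched version or truncated file raises
instead of silently coercing.

## Known limitations

The STM likelihood is non-concave; EM initialization plus L-BFGS gives
stable optima in practice (the factored variant is stable across random
seeds to < 0.03 bits/bin in the tests) but global optimality is not
guaranteed.  The quadratic model at D = 10 already carries 166
parameters, so very short recordings favor the factored variant.  L2 is
the only built-in regularizer besides early stopping.  Poisson or other
count observation models are out of scope — the package is strictly
Bernoulli-per-bin.
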