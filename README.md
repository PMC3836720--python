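# spikemix

Probabilistic system identification for single neurons: fit and compare
Bernoulli-per-bin encoding models of spike trains — the generalized
linear model (GLM), the quadratic model, the **spike-triggered mixture
model (STM)** and its low-rank **factored** variant — with generative
initialization, discriminative training, spike-history modelling, and an
evaluation suite built on cross-entropy, mutual-information lower bounds
and the PSTH oracle.

## Who it is for

Anyone modelling binned binary spike responses `y_t ∈ {0, 1}` to a
time-varying stimulus: sensory physiologists characterizing single
units, and methods researchers who need a flexible yet parameter-frugal
alternative to GLMs that still trains with standard quasi-Newton
optimizers.

## The model

All families predict the per-bin spike probability as `σ(f(x_t, s_t))`,
where `x_t` are stimulus features (e.g. PCA projections of a short
stimulus window), `s_t` is a one-hot vector marking the most recent
spike within a history window, and `σ` is the logistic function.  The
STM predictor is

    f(x, s) = log Σ_k exp(½ x'A_k x + w_k'x + a_k) + h's,

a *soft maximum* of K quadratic models — exactly the Bayes posterior
log-odds when the spike-triggered stimulus distribution is a Gaussian
mixture and the non-spike-triggered distribution a single Gaussian.  The
history filter `h` is the log-ratio of interspike-interval histograms
(naive Bayes).  The factored STM replaces each `A_k` by shared low-rank
features, `Σ_m β_km (u_m'x)²`, so its parameter count `MD + KM + KD + K + H`
grows linearly in the stimulus dimension — 246 parameters at
D = 10, H = 100, K = 6, M = 5, where a dense STM of the same K would
need far more.  With K = 1 the STM reduces to the quadratic model; with
A = 0 to the GLM.

STM fitting initializes generatively (EM on the spike-triggered
distribution, one Gaussian for the rest, ISI histograms for the history
filter) and then fine-tunes all parameters discriminatively with L-BFGS
on the conditional likelihood.  GLM and quadratic models optionally get
the multi-step treatment: concave sigmoid fit, then a flexible
sum-of-Gaussian-blobs nonlinearity, then a 150-bin histogram
nonlinearity.  Details are in `docs/methods.md`.

## Worked example

```python
import numpy as np
import spikemix as sm

# a synthetic session: STM ground truth, 2 unfrozen + 1 frozen trial
design = sm.ExperimentDesign(trial_length=6.5, n_pc=5,
                             n_unfrozen=2, n_frozen=2)
neuron = sm.make_ground_truth("stm", design, seed=3, target_rate=50.0)
exp = sm.simulate_experiment(neuron, seed=10)

model = sm.STM(exp.train_y, exp.train_X, exp.train_S,
               dt=design.dt, n_components=3)
res = model.fit(sm.TrainConfig(max_iter=400))
print(res.summary())

test = ((exp.frozen_X, exp.frozen_S_per_trial[0]),
        exp.frozen_trials[0].counts)
print("held-out CE:", res.cross_entropy(*test).cross_entropy_bits_per_bin)
print("true-model CE:", sm.bernoulli_nll(neuron.params, *test))
```

prints (numbers from this exact script):

```
Bernoulli encoding model fit
==========================================
family:            stm
components K:      3
bins:              52000
bin width:         0.250 ms
stimulus dim D:    5
history dim H:     100
parameters:        163
spike rate:        54.62 Hz
train CE:          0.0821 bits/bin
early stopping:    no
held-out CE: 0.07848534260209228
true-model CE: 0.07526927544236758
```

The fitted STM's held-out cross-entropy lands within ~0.003 bits/bin of
the generating model's own — the model class is recovered from 13 s of
simulated data.  Fitting `BernoulliGLM` and `QuadraticModel` on the same
data gives 0.0886 and 0.0793 bits/bin: the characteristic ordering
GLM ≥ quadratic ≥ STM.

A command-line layer wraps the same pipeline
(`spikemix simulate | fit | evaluate | compare`); every artifact-writing
command records a manifest with seeds and a config hash.

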