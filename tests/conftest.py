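import numpy as np
import pytest

import spikemix as sm


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def _fit_three_families(seed):
    """Simulate a K=3 STM neuron (D=5, ~50k training bins) and fit the
    three sigmoid families; returns held-out cross-entropies."""
    design = sm.ExperimentDesign(trial_length=6.5, n_pc=5,
                                 n_unfrozen=2, n_frozen=2)
    neuron = sm.make_ground_truth("stm", design, seed=seed, target_rate=50.0)
    exp = sm.simulate_experiment(neuron, seed=seed + 1000)
    Xtr, Str, ytr = exp.train_X, exp.train_S, exp.train_y
    Xte = exp.frozen_X
    Ste = exp.frozen_S_per_trial[0]
    yte = exp.frozen_trials[0].counts
    test = ((Xte, Ste), yte)
    cfg = sm.TrainConfig(max_iter=400)
    out = {"true": sm.bernoulli_nll(neuron.params, *test)}
    out["glm"] = sm.bernoulli_nll(
        sm.BernoulliGLM(ytr, Xtr, Str, dt=design.dt).fit(cfg).params, *test)
    out["quad"] = sm.bernoulli_nll(
        sm.QuadraticModel(ytr, Xtr, Str, dt=design.dt).fit(cfg).params, *test)
    out["stm"] = sm.bernoulli_nll(
        sm.STM(ytr, Xtr, Str, dt=design.dt, n_components=3).fit(cfg).params,
        *test)
    return out


@pytest.fixture(scope="session")
def recovery_study():
    """Held-out cross-entropies of GLM/quadratic/STM fits on data from
    seeded K=3 STM neurons, over 10 seeds.  Shared by the recovery and
    model-ordering checks."""
    return [_fit_three_families(seed) for seed in range(10)]


@pytest.fixture(scope="session")
def historyfree_frozen_session():
    """Frozen trials from a history-free STM neuron, for PSTH checks."""
    design = sm.ExperimentDesign(trial_length=4.0, n_pc=5, n_frozen=30)
    neuron = sm.make_ground_truth("stm", design, seed=7, target_rate=60.0)
    params = neuron.params.copy()
    params.h = np.zeros_like(params.h)  # strip history dependence
    neuron = sm.GroundTruthNeuron(params, design, neuron.seed, pca=neuron.pca)
    wave = sm.generate_stimulus(design.trial_length + design.window,
                                design.fs, design.cutoff, seed=71)
    trials = sm.sample_spike_train(neuron, wave, n_trials=30, seed=72)
    from spikemix.simulate import extract_windows
    windows, _ = extract_windows(wave, design)
    X = neuron.pca.project(windows)[:len(trials[0])]
    return {"neuron": neuron, "trials": trials, "X": X, "design": design}
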