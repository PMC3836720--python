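"""Simulated experiments: stimuli, designs and ground-truth neurons.

The simulator emulates a white-noise single-unit protocol: a low-pass
filtered Gaussian noise waveform drives a model neuron; short stimulus
windows preceding each bin are reduced by PCA to a feature vector; the
spike history enters as a one-hot most-recent-spike vector.  Trials come
in two flavors — *unfrozen* (a fresh waveform per trial) and *frozen*
(one waveform repeated), the latter enabling PSTH-based evaluation.

Defaults: 4 kHz waveform sampling, 0.25 ms bins (so one history bin of the
25 ms / 100-bin window equals one spike bin), 10 ms windows, 10 principal
components.  Spike sampling is sequential because the history vector at
bin t depends on the spikes sampled before t.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt, periodogram
from scipy.special import expit

from .containers import (BinnedSpikeTrain, ExperimentDesign, HistoryDesign,
                         StimulusDesign)
from .generative import time_since_last_spike
from .params import (FactoredSTMParams, GLMParams, QuadraticParams, STMParams,
                     component_responses, predictor)
from .training import design_arrays, spike_array


@dataclass
class StimulusWaveform:
    """Low-pass filtered Gaussian noise stimulus."""

    samples: np.ndarray
    fs: float
    cutoff: float

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if not self.fs > 2 * self.cutoff:
            raise ValueError("sampling rate must exceed twice the cutoff")
        if not np.isfinite(self.samples).all():
            raise ValueError("waveform contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


def generate_stimulus(duration: float, fs: float = 4000.0,
                      cutoff: float = 100.0, seed: int = 0) -> StimulusWaveform:
    """Seeded Gaussian white noise, zero-phase low-pass filtered at
    ``cutoff`` (4th-order Butterworth), standardized to zero mean and unit
    variance."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    if fs <= 2 * cutoff:
        raise ValueError("fs must exceed twice the cutoff frequency")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    white = rng.standard_normal(n)
    b, a = butter(4, cutoff / (fs / 2.0))
    x = filtfilt(b, a, white)
    x = (x - x.mean()) / x.std()
    return StimulusWaveform(x, fs, cutoff)


def highband_power_fraction(waveform: StimulusWaveform) -> float:
    """Fraction of total spectral power above twice the cutoff."""
    freqs, pxx = periodogram(waveform.samples, waveform.fs)
    return float(pxx[freqs > 2 * waveform.cutoff].sum() / pxx.sum())


class StimulusPCA:
    """PCA basis over stimulus windows, fitted on training windows only and
    reused for test data.  No whitening: projections keep their natural
    variance."""

    def __init__(self, mean, components):
        self.mean = np.asarray(mean, dtype=float)
        self.components = np.asarray(components, dtype=float)  # (n_pc, win)

    @classmethod
    def fit(cls, windows, n_pc: int):
        windows = np.asarray(windows, dtype=float)
        mean = windows.mean(axis=0)
        _, _, Vt = np.linalg.svd(windows - mean, full_matrices=False)
        if n_pc > Vt.shape[0]:
            raise ValueError(
                f"requested {n_pc} components but windows have rank {Vt.shape[0]}"
            )
        return cls(mean, Vt[:n_pc])

    def project(self, windows):
        return (np.asarray(windows, dtype=float) - self.mean) @ self.components.T

    def reconstruct(self, projected):
        return np.asarray(projected) @ self.components + self.mean


def extract_windows(waveform: StimulusWaveform, design: ExperimentDesign):
    """Stimulus windows strictly preceding each bin.

    Returns ``(windows, first_bin)``: row i holds the ``window`` seconds of
    stimulus before bin ``first_bin + i``; bins without a full window are
    dropped and ``first_bin`` reports how many.
    """
    spb = int(round(waveform.fs * design.dt))
    if spb < 1:
        raise ValueError("waveform sampling must be at least one sample per bin")
    ws = int(round(design.window * waveform.fs))
    n_bins = waveform.samples.size // spb
    first_bin = int(np.ceil(ws / spb))
    if first_bin >= n_bins:
        raise ValueError("waveform shorter than one stimulus window")
    idx = (np.arange(first_bin, n_bins)[:, None] * spb
           + np.arange(-ws, 0)[None, :])
    return waveform.samples[idx], first_bin


def history_matrix(counts, history_bins: int, ratio: int = 1) -> np.ndarray:
    """One-hot most-recent-spike encoding of a binned train.

    ``ratio`` is the number of spike bins per history bin.  A spike in the
    immediately preceding spike bin maps to history index 0; bins with no
    spike inside the window get an all-zero row.
    """
    counts = np.asarray(counts)
    ages = time_since_last_spike(counts)  # bins since last spike; -1 if none
    T = counts.size
    S = np.zeros((T, history_bins))
    valid = ages > 0
    j = (ages[valid] - 1) // ratio
    keep = j < history_bins
    rows = np.flatnonzero(valid)[keep]
    S[rows, j[keep]] = 1.0
    return S


@dataclass
class DesignResult:
    """Aligned per-bin designs built from a waveform and a spike train."""

    stimulus: StimulusDesign
    history: HistoryDesign
    spikes: BinnedSpikeTrain
    pca: StimulusPCA
    n_dropped: int


def build_design(waveform: StimulusWaveform, spikes: BinnedSpikeTrain,
                 design: ExperimentDesign,
                 pca: StimulusPCA | None = None) -> DesignResult:
    """Per-bin stimulus features and history vectors.

    ``x_t`` is the PCA projection of the ``window`` seconds of stimulus
    strictly preceding bin t (causal); ``s_t`` is the one-hot position of
    the most recent spike within the history window.  Bins at the start
    without a full stimulus window are dropped; the count is reported.
    Pass a fitted ``pca`` to reuse a training basis on test data.
    """
    windows, first_bin = extract_windows(waveform, design)
    T = len(spikes)
    n_avail = windows.shape[0]
    if T > first_bin + n_avail:
        raise ValueError("waveform does not cover all spike-train bins")
    windows = windows[:T - first_bin]
    if pca is None:
        pca = StimulusPCA.fit(windows, design.n_pc)
    X = pca.project(windows)
    ratio = int(round(design.history_bin_width / design.dt))
    S_full = history_matrix(spikes.counts, design.history_bins, ratio)
    trimmed = BinnedSpikeTrain(spikes.counts[first_bin:T], spikes.dt,
                               spikes.trial_id)
    return DesignResult(StimulusDesign(X), HistoryDesign(S_full[first_bin:T]),
                        trimmed, pca, first_bin)


# ---------------------------------------------------------------------------
# spike sampling with history feedback

def _stimulus_drive(params, X):
    """Per-bin predictor contribution that does not depend on history."""
    if isinstance(params, GLMParams):
        return X @ params.w + params.b
    if isinstance(params, QuadraticParams):
        return (0.5 * np.einsum("td,de,te->t", X, params.A, X)
                + X @ params.w + params.b)
    if isinstance(params, (STMParams, FactoredSTMParams)):
        from scipy.special import logsumexp
        return logsumexp(component_responses(params, X), axis=1)
    if hasattr(params, "base"):  # flexible-LN models: no closed stim drive
        raise TypeError("sampling requires a sigmoid-family parameter set")
    raise TypeError(f"unknown parameter family: {type(params).__name__}")


def sample_from_features(params, X, seed: int = 0,
                         ratio: int = 1) -> np.ndarray:
    """Sample a binary train from per-bin features with history feedback.

    The history vector at bin t is rebuilt from the spikes sampled so far,
    so sampling is sequential.  History-free parameter sets (H = 0 or an
    all-zero filter) are sampled fully vectorized.
    """
    rng = np.random.default_rng(seed)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    T = X.shape[0]
    drive = _stimulus_drive(params, X)
    h = params.h
    u = rng.random(T)
    if h.size == 0 or not np.any(h):
        return (u < expit(drive)).astype(np.int8)
    H = h.size
    y = np.zeros(T, dtype=np.int8)
    last = -1
    hb = H * ratio  # history span in spike bins
    for t in range(T):
        f = drive[t]
        if last >= 0 and t - last <= hb:
            f = f + h[(t - last - 1) // ratio]
        if u[t] < expit(f):
            y[t] = 1
            last = t
    return y


@dataclass
class GroundTruthNeuron:
    """A known parameter set together with the experiment layout used to
    simulate it (and the PCA basis its features live in)."""

    params: object
    design: ExperimentDesign
    seed: int
    pca: StimulusPCA | None = None
    target_rate: float | None = None

    @property
    def ratio(self) -> int:
        return int(round(self.design.history_bin_width / self.design.dt))


def sample_spike_train(neuron: GroundTruthNeuron, waveform: StimulusWaveform,
                       n_trials: int = 1, seed: int = 0):
    """Sample spike trains from a neuron driven by a waveform.

    Every trial uses the same waveform (frozen-trial style) but fresh
    Bernoulli noise and history feedback; per-trial seeds derive from
    ``seed``.  Returns trains aligned with the design bins (initial bins
    without a full stimulus window are absent).
    """
    ref = BinnedSpikeTrain(np.zeros(
        min(neuron.design.bins_per_trial,
            int(waveform.duration / neuron.design.dt)), dtype=int),
        neuron.design.dt)
    built = build_design(waveform, ref, neuron.design, pca=neuron.pca)
    X = built.stimulus.X
    trains = []
    for r in range(n_trials):
        y = sample_from_features(neuron.params, X, seed=seed + 7919 * r,
                                 ratio=neuron.ratio)
        trains.append(BinnedSpikeTrain(y, neuron.design.dt, trial_id=r))
    return trains


def _shift_bias(params, delta: float):
    p = params.copy()
    if isinstance(p, (GLMParams, QuadraticParams)):
        p.b += delta
    else:
        p.a = p.a + delta
    return p


def _mean_rate(params, X, dt, ratio, seed):
    y = sample_from_features(params, X, seed=seed, ratio=ratio)
    return y.mean() / dt


def calibrate_bias(params, X, dt: float, target_rate: float, ratio: int = 1,
                   seed: int = 0, tol: float = 0.02, max_steps: int = 100):
    """Shift the model's bias until the simulated mean rate matches
    ``target_rate`` (Hz) via bisection; raises if it fails to bracket or
    converge within ``max_steps``."""
    lo, hi = -30.0, 30.0
    if not (_mean_rate(_shift_bias(params, lo), X, dt, ratio, seed)
            < target_rate <
            _mean_rate(_shift_bias(params, hi), X, dt, ratio, seed)):
        raise RuntimeError("could not bracket the target firing rate")
    for step in range(max_steps):
        mid = (lo + hi) / 2.0
        rate = _mean_rate(_shift_bias(params, mid), X, dt, ratio, seed + step)
        if abs(rate - target_rate) <= tol * target_rate:
            return _shift_bias(params, mid)
        if rate < target_rate:
            lo = mid
        else:
            hi = mid
    raise RuntimeError(
        f"bias calibration did not converge in {max_steps} bisection steps"
    )


def make_ground_truth(kind: str, design: ExperimentDesign | None = None,
                      seed: int = 0, target_rate: float = 50.0,
                      n_components: int = 3,
                      refractory_strength: float = 8.0) -> GroundTruthNeuron:
    """Draw a seeded ground-truth neuron of a given family.

    Filters are drawn relative to the feature scales of a calibration
    stimulus so every family produces a comparable drive, the history
    filter imposes an exponentially decaying refractory suppression, and
    the bias is calibrated by bisection so the simulated mean rate hits
    ``target_rate`` (default 50 Hz, within the physiological 20-120 Hz
    range of the source preparation).
    """
    design = design or ExperimentDesign()
    rng = np.random.default_rng(seed)
    cal_dur = min(5.0, design.trial_length)
    wave = generate_stimulus(cal_dur + design.window, design.fs,
                             design.cutoff, seed=rng.integers(2 ** 31))
    windows, _ = extract_windows(wave, design)
    pca = StimulusPCA.fit(windows, design.n_pc)
    X = pca.project(windows)
    sd = X.std(axis=0)
    D, H = design.n_pc, design.history_bins
    h = -refractory_strength * np.exp(-np.arange(H) / 8.0)

    def draw_w():
        return rng.normal(0.0, 1.0, D) / (sd * np.sqrt(D)) * 2.0

    def draw_A():
        R = rng.normal(0.0, 0.3 / np.sqrt(D), (D, D))
        return (R + R.T) / np.outer(sd, sd) / 2.0

    kind = kind.lower()
    if kind == "glm":
        params = GLMParams(draw_w(), h, 0.0)
    elif kind in ("quadratic", "quad"):
        params = QuadraticParams(draw_A(), draw_w(), h, 0.0)
    elif kind == "stm":
        K = n_components
        params = STMParams(np.stack([draw_A() for _ in range(K)]),
                           np.stack([draw_w() for _ in range(K)]),
                           rng.normal(0.0, 1.0, K) - np.log(K), h)
    else:
        raise ValueError(f"unknown ground-truth kind: {kind!r}")
    ratio = int(round(design.history_bin_width / design.dt))
    params = calibrate_bias(params, X, design.dt, target_rate, ratio=ratio,
                            seed=int(rng.integers(2 ** 31)))
    return GroundTruthNeuron(params, design, seed, pca=pca,
                             target_rate=target_rate)


@dataclass
class SimulatedExperiment:
    """Outputs of a full simulated session: concatenated training designs
    from unfrozen trials and frozen-trial responses to one repeated
    waveform."""

    train_X: np.ndarray
    train_S: np.ndarray
    train_y: np.ndarray
    frozen_trials: list
    frozen_X: np.ndarray
    frozen_S_per_trial: list
    pca: StimulusPCA
    design: ExperimentDesign


def simulate_experiment(neuron: GroundTruthNeuron, seed: int = 0,
                        n_unfrozen: int | None = None,
                        n_frozen: int | None = None) -> SimulatedExperiment:
    """Run a session: fresh waveforms for unfrozen (training) trials, one
    repeated waveform for frozen (test) trials."""
    design = neuron.design
    nu = design.n_unfrozen if n_unfrozen is None else n_unfrozen
    nf = design.n_frozen if n_frozen is None else n_frozen
    rng = np.random.default_rng(seed)
    Xs, Ss, ys = [], [], []
    for r in range(nu):
        wave = generate_stimulus(design.trial_length + design.window,
                                 design.fs, design.cutoff,
                                 seed=int(rng.integers(2 ** 31)))
        built = build_design(
            wave, BinnedSpikeTrain(
                np.zeros(int(wave.duration / design.dt), dtype=int), design.dt),
            design, pca=neuron.pca)
        y = sample_from_features(neuron.params, built.stimulus.X,
                                 seed=int(rng.integers(2 ** 31)),
                                 ratio=neuron.ratio)
        S = history_matrix(y, design.history_bins, neuron.ratio)
        Xs.append(built.stimulus.X)
        Ss.append(S)
        ys.append(y)
    frozen_wave = generate_stimulus(design.trial_length + design.window,
                                    design.fs, design.cutoff,
                                    seed=int(rng.integers(2 ** 31)))
    frozen = sample_spike_train(neuron, frozen_wave, n_trials=nf,
                                seed=int(rng.integers(2 ** 31)))
    n_ref = min(design.bins_per_trial,
                int(frozen_wave.duration / design.dt))
    built_f = build_design(
        frozen_wave, BinnedSpikeTrain(np.zeros(n_ref, dtype=int), design.dt),
        design, pca=neuron.pca)
    frozen_S = [history_matrix(tr.counts, design.history_bins, neuron.ratio)
                for tr in frozen]
    return SimulatedExperiment(
        np.vstack(Xs), np.vstack(Ss), np.concatenate(ys),
        frozen, built_f.stimulus.X, frozen_S, neuron.pca, design)
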