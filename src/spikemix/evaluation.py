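"""Model evaluation: cross-entropy, information lower bounds, PSTH oracle.

Cross-entropy (bits per bin) is the held-out negative log-likelihood of
the spike train; dividing by the bin width gives bits per second.  The
difference between the cross-entropy of a history-only model and a full
model lower-bounds the information the spike train carries about the
stimulus.  The PSTH oracle predicts each frozen trial from the
kernel-smoothed leave-one-out average of the remaining trials — an
optimistic benchmark for any history-free model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr, wilcoxon

from .containers import BinnedSpikeTrain
from .training import PROB_FLOOR, bernoulli_nll, design_arrays, spike_array

PSTH_CLIP = 1.0 - 1e-9
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class EvalReport:
    """Held-out performance of one model on one test set."""

    cross_entropy_bits_per_bin: float
    cross_entropy_bits_per_s: float
    mi_lower_bound_bits_per_s: float | None
    n_test_bins: int
    dt: float

    def __post_init__(self):
        if self.n_test_bins < 1:
            raise ValueError("need at least one test bin")
        expected = self.cross_entropy_bits_per_bin / self.dt
        if abs(self.cross_entropy_bits_per_s - expected) > 1e-9 * max(1, abs(expected)):
            raise ValueError("bits/s must equal bits/bin divided by dt")


@dataclass
class PSTHModel:
    """Leave-one-out smoothed-PSTH predictor for a set of frozen trials."""

    kernel_fwhm: float
    offset: float
    predictions: np.ndarray  # (n_trials, n_bins): prediction for held-out trial r
    dt: float

    def __post_init__(self):
        if self.kernel_fwhm <= 0 or self.offset <= 0:
            raise ValueError("kernel_fwhm and offset must be positive")
        if (self.predictions <= 0).any() or (self.predictions > 1).any():
            raise ValueError("PSTH predictions must lie in (0, 1]")

    def cross_entropy_bits_per_bin(self, trials) -> float:
        """Mean Bernoulli cross-entropy of each trial under its own
        leave-one-out prediction."""
        Y = _trial_matrix(trials)[0]
        p = np.clip(self.predictions, PROB_FLOOR, PSTH_CLIP)
        return float(-np.mean(Y * np.log2(p) + (1 - Y) * np.log2(1 - p)))


def cross_entropy(params, design, spikes, dt: float,
                  history_only_report: "EvalReport | None" = None) -> EvalReport:
    """Evaluate a model's cross-entropy on held-out data.

    If a history-only report on the same test set is supplied, the
    stimulus-information lower bound is filled in as well.
    """
    y = spike_array(spikes)
    ce = bernoulli_nll(params, design, spikes)
    mi = None
    if history_only_report is not None:
        mi = (history_only_report.cross_entropy_bits_per_bin - ce) / dt
    return EvalReport(ce, ce / dt, mi, y.size, dt)


def mi_lower_bound(stim_model_report: EvalReport,
                   history_only_report: EvalReport) -> float:
    """Stimulus-information rate estimate in bits per second.

    ``(CE_historyOnly - CE_full) / dt``; the better the full model, the
    tighter the bound.  May be negative for models worse than the
    history-only baseline.
    """
    if stim_model_report.n_test_bins != history_only_report.n_test_bins or \
            abs(stim_model_report.dt - history_only_report.dt) > 1e-12:
        raise ValueError("reports must come from the same test set and dt")
    return (history_only_report.cross_entropy_bits_per_bin
            - stim_model_report.cross_entropy_bits_per_bin) / stim_model_report.dt


def _trial_matrix(trials):
    trials = list(trials)
    if len(trials) < 2:
        raise ValueError("need at least two frozen trials")
    lengths = {len(tr) for tr in trials}
    if len(lengths) > 1:
        raise ValueError("frozen trials must have equal length")
    dts = {tr.dt for tr in trials}
    if len(dts) > 1:
        raise ValueError("frozen trials must share dt")
    Y = np.stack([np.asarray(tr.counts, dtype=float) for tr in trials])
    return Y, trials[0].dt


def gaussian_kernel(fwhm: float, dt: float) -> np.ndarray:
    """Discrete Gaussian kernel (unit sum) truncated at +/- 4 sigma."""
    sigma = max(fwhm * FWHM_TO_SIGMA, 1e-12)
    half = max(1, int(np.ceil(4.0 * sigma / dt)))
    t = np.arange(-half, half + 1) * dt
    k = np.exp(-0.5 * (t / sigma) ** 2)
    return k / k.sum()


def smooth_rate(counts, fwhm: float, dt: float) -> np.ndarray:
    """Kernel-smoothed per-bin spike probability of one train.

    Edges are renormalized by the local kernel mass so a constant train
    smooths to the same constant.
    """
    counts = np.asarray(counts, dtype=float)
    k = gaussian_kernel(fwhm, dt)
    half = (k.size - 1) // 2
    num = np.convolve(counts, k, mode="full")[half:half + counts.size]
    den = np.convolve(np.ones_like(counts), k,
                      mode="full")[half:half + counts.size]
    return num / den


def psth_predict(frozen_trials, kernel_fwhm: float, offset: float) -> PSTHModel:
    """Leave-one-trial-out PSTH predictions for each frozen trial.

    For trial r, the predicted spike probability per bin is the offset
    plus the kernel-smoothed mean response of the other N-1 trials,
    clipped to at most 1.
    """
    Y, dt = _trial_matrix(frozen_trials)
    n = Y.shape[0]
    smoothed = np.stack([smooth_rate(row, kernel_fwhm, dt) for row in Y])
    total = smoothed.sum(axis=0)
    loo = (total[None, :] - smoothed) / (n - 1)
    preds = np.minimum(loo + offset, PSTH_CLIP)
    return PSTHModel(kernel_fwhm, offset, preds, dt)


def select_psth_params(frozen_trials, fwhm_grid=None, offset_grid=None):
    """Grid-search the kernel width and offset minimizing the mean
    leave-one-out cross-entropy; ties break toward the wider kernel, then
    the larger offset."""
    if fwhm_grid is None:
        fwhm_grid = np.geomspace(0.05e-3, 5e-3, 9)
    if offset_grid is None:
        offset_grid = np.geomspace(1e-4, 1e-1, 7)
    fwhm_grid = np.asarray(list(fwhm_grid), dtype=float)
    offset_grid = np.asarray(list(offset_grid), dtype=float)
    if fwhm_grid.size == 0 or offset_grid.size == 0:
        raise ValueError("parameter grids must be nonempty")
    best = None
    for fwhm in np.sort(fwhm_grid)[::-1]:          # wider kernels first
        for offset in np.sort(offset_grid)[::-1]:  # larger offsets first
            model = psth_predict(frozen_trials, fwhm, offset)
            score = model.cross_entropy_bits_per_bin(frozen_trials)
            if best is None or score < best[0] - 1e-15:
                best = (score, fwhm, offset)
    return best[1], best[2]


def explained_variance(model_psth, reference_psth) -> float:
    """Squared Pearson correlation between two smoothed rate vectors."""
    a = np.asarray(model_psth, dtype=float).ravel()
    b = np.asarray(reference_psth, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("rate vectors must have equal length")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("explained variance undefined for constant rates")
    return float(pearsonr(a, b).statistic ** 2)


def paired_signed_rank(improvements, alternative: str = "greater"):
    """One-tailed Wilcoxon signed-rank test on per-cell paired differences
    (thin wrapper around the standard routine)."""
    return wilcoxon(np.asarray(improvements, dtype=float),
                    alternative=alternative)
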