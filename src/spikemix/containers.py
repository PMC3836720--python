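"""Basic data containers: binned spike trains and per-bin design matrices.

The models in this package are Bernoulli-per-bin encoding models: the
response is a binary sequence ``y_t`` (spike / no spike in bin ``t``), the
inputs are a stimulus feature vector ``x_t`` (dimension D, typically a PCA
projection of a short stimulus window preceding the bin) and a spike-history
vector ``s_t`` (dimension H, one-hot at the position of the most recent
spike within the history window, or all zero if there is none).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class BinnedSpikeTrain:
    """Binary spike counts on a regular time grid.

    Parameters
    ----------
    counts : array of int
        One entry per bin, each 0 or 1.
    dt : float
        Bin width in seconds.
    trial_id : int or str
        Identifier of the trial the train belongs to.
    """

    counts: np.ndarray
    dt: float
    trial_id: object = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1 or self.counts.size < 1:
            raise ValueError("counts must be a non-empty 1-d array")
        if not np.isin(self.counts, (0, 1)).all():
            raise ValueError("counts must be binary (0 or 1 per bin)")
        self.counts = self.counts.astype(np.int8)
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    def __len__(self):
        return self.counts.size

    @property
    def n_spikes(self) -> int:
        return int(self.counts.sum())

    @property
    def duration(self) -> float:
        return self.counts.size * self.dt

    def spike_times(self) -> np.ndarray:
        """Bin-center times (seconds) of the bins containing a spike."""
        return (np.flatnonzero(self.counts) + 0.5) * self.dt


@dataclass
class StimulusDesign:
    """Per-bin stimulus feature vectors, one length-D row per bin."""

    X: np.ndarray

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[1] < 1:
            raise ValueError("stimulus dimension D must be >= 1")

    @property
    def n_bins(self) -> int:
        return self.X.shape[0]

    @property
    def dim(self) -> int:
        return self.X.shape[1]


@dataclass
class HistoryDesign:
    """Per-bin most-recent-spike indicators.

    Each row has at most one nonzero entry, equal to 1, at the history-bin
    index of the most recent spike (index 0 = the immediately preceding
    history bin).  An all-zero row means no spike within the window.
    """

    S: np.ndarray

    def __post_init__(self):
        self.S = np.atleast_2d(np.asarray(self.S, dtype=float))
        nonzero_per_row = (self.S != 0).sum(axis=1)
        if (nonzero_per_row > 1).any():
            raise ValueError("each history row may have at most one nonzero entry")
        if not np.isin(self.S[self.S != 0], 1.0).all():
            raise ValueError("nonzero history entries must equal 1")

    @property
    def n_bins(self) -> int:
        return self.S.shape[0]

    @property
    def dim(self) -> int:
        return self.S.shape[1]


@dataclass
class ExperimentDesign:
    """Layout of a simulated experiment.

    Defaults mirror a whisker-afferent white-noise protocol: 50 unfrozen
    trials (fresh stimulus per trial) and 50 frozen trials (one stimulus
    repeated), 10 ms stimulus windows reduced to 10 principal components,
    and 25 ms of spike history in 100 equal bins with all but the most
    recent spike removed.
    """

    n_unfrozen: int = 50
    n_frozen: int = 50
    trial_length: float = 10.0
    dt: float = 0.00025
    window: float = 0.010
    n_pc: int = 10
    history_window: float = 0.025
    history_bins: int = 100
    fs: float = 4000.0
    cutoff: float = 100.0

    def __post_init__(self):
        if self.window <= 0:
            raise ValueError("window must be positive")
        if self.history_bins < 1:
            raise ValueError("history_bins must be >= 1")
        hbw = self.history_window / self.history_bins
        if abs(hbw / self.dt - round(hbw / self.dt)) > 1e-9:
            raise ValueError(
                "history-bin width (history_window / history_bins) must be an "
                "integer multiple of dt"
            )

    @property
    def history_bin_width(self) -> float:
        return self.history_window / self.history_bins

    @property
    def bins_per_trial(self) -> int:
        return int(round(self.trial_length / self.dt))
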