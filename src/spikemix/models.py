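"""Model / Results classes binding the functional core together.

The API follows the familiar modelling-package pattern: construct a model
from data, call :meth:`fit`, inspect the returned results object.

>>> model = STM(spikes, stimulus, history, dt=0.00025, n_components=3)
>>> res = model.fit()
>>> print(res.summary())
>>> res.cross_entropy(test_design, test_spikes)

``BernoulliGLM`` and ``QuadraticModel`` support ``nonlinearity="flexible"``
to run the multi-step recipe (sigmoid fit, blob nonlinearity, histogram
nonlinearity); ``STM`` is initialized generatively (EM on the
spike-triggered distribution, a single non-spike-triggered Gaussian and
interspike-interval histograms) and fine-tuned discriminatively;
``FactoredSTM`` trains from a random initialization.
"""

from __future__ import annotations

import numpy as np

from .containers import BinnedSpikeTrain
from .evaluation import EvalReport, cross_entropy as _cross_entropy
from .generative import (bayes_to_stm, estimate_isi, fit_gaussian, fit_mog_em,
                         isi_to_history_filter)
from .params import (FactoredSTMParams, GLMParams, QuadraticParams, STMParams,
                     count_parameters, family_of, firing_prob)
from .simulate import sample_from_features
from .training import (FitResult, TrainConfig, bernoulli_nll, design_arrays,
                       finetune, fit_factored_stm, fit_glm_pipeline,
                       spike_array)


class BernoulliEncodingModel:
    """Base class: binary spike train regressed on per-bin designs.

    Parameters
    ----------
    spikes : BinnedSpikeTrain or binary array
        The response, one 0/1 entry per bin.
    stimulus : array (T, D) or None
        Stimulus feature vectors.
    history : array (T, H) or None
        One-hot most-recent-spike vectors.
    dt : float
        Bin width in seconds (taken from ``spikes`` when it is a
        BinnedSpikeTrain).
    """

    family = None

    def __init__(self, spikes, stimulus=None, history=None, dt=None):
        if isinstance(spikes, BinnedSpikeTrain):
            dt = spikes.dt if dt is None else dt
        if dt is None:
            raise ValueError("dt is required when spikes is a plain array")
        self.endog = spike_array(spikes)
        self.exog, self.exog_history = design_arrays((stimulus, history))
        if self.exog.shape[0] != self.endog.size:
            raise ValueError("design rows must match the number of bins")
        self.dt = float(dt)

    @property
    def n_bins(self):
        return self.endog.size

    @property
    def dim(self):
        return self.exog.shape[1]

    @property
    def history_dim(self):
        return self.exog_history.shape[1]

    @property
    def spike_rate(self):
        return float(self.endog.mean())

    def _design(self):
        return (self.exog, self.exog_history)

    @classmethod
    def from_dataframe(cls, frame, spike_col="spike", stimulus_prefix="x",
                       history_prefix="s", dt=None, **kwargs):
        """Build a model from a tidy DataFrame with one row per bin."""
        stim_cols = [c for c in frame.columns
                     if str(c).startswith(stimulus_prefix) and c != spike_col]
        hist_cols = [c for c in frame.columns
                     if str(c).startswith(history_prefix) and c != spike_col]
        X = frame[stim_cols].to_numpy(float) if stim_cols else None
        S = frame[hist_cols].to_numpy(float) if hist_cols else None
        return cls(frame[spike_col].to_numpy(), X, S, dt=dt, **kwargs)

    def _wrap(self, fit_result: FitResult):
        return EncodingResults(self, fit_result)


class BernoulliGLM(BernoulliEncodingModel):
    """Linear-nonlinear-Bernoulli model (sigmoid or flexible nonlinearity)."""

    family = "glm"

    def fit(self, config: TrainConfig | None = None, val_split=None,
            nonlinearity: str = "sigmoid") -> "EncodingResults":
        if nonlinearity == "flexible":
            return self._wrap(fit_glm_pipeline(
                self._design(), self.endog, "linear", config, val_split))
        b0 = _rate_logit(self.spike_rate)
        init = GLMParams(np.zeros(self.dim), np.zeros(self.history_dim), b0)
        return self._wrap(finetune(init, self._design(), self.endog, config,
                                   val_split))


class QuadraticModel(BernoulliEncodingModel):
    """Bernoulli model with a full quadratic form in the stimulus."""

    family = "quadratic"

    def fit(self, config: TrainConfig | None = None, val_split=None,
            nonlinearity: str = "sigmoid") -> "EncodingResults":
        if nonlinearity == "flexible":
            return self._wrap(fit_glm_pipeline(
                self._design(), self.endog, "quadratic", config, val_split))
        b0 = _rate_logit(self.spike_rate)
        init = QuadraticParams(np.zeros((self.dim, self.dim)),
                               np.zeros(self.dim),
                               np.zeros(self.history_dim), b0)
        return self._wrap(finetune(init, self._design(), self.endog, config,
                                   val_split))


class STM(BernoulliEncodingModel):
    """Spike-triggered mixture model.

    ``fit`` estimates the spike-triggered distribution as a
    ``n_components``-Gaussian mixture by EM, the non-spike-triggered
    distribution as a single Gaussian, converts them through Bayes' rule
    into predictor parameters, initializes the history filter from
    interspike-interval histograms, and fine-tunes everything by
    maximizing the conditional likelihood.
    """

    family = "stm"

    def __init__(self, spikes, stimulus=None, history=None, dt=None,
                 n_components: int = 3):
        super().__init__(spikes, stimulus, history, dt)
        if n_components < 1:
            raise ValueError("need at least one mixture component")
        self.n_components = n_components

    def init_generative(self, seed: int = 0) -> STMParams:
        """Generative initialization (EM + Bayes rule + ISI histograms)."""
        y = self.endog.astype(bool)
        if y.sum() < 2 or (~y).sum() < 2:
            raise ValueError("need spikes and non-spikes to initialize")
        mix1, _ = fit_mog_em(self.exog[y], self.n_components, seed=seed)
        gauss0 = fit_gaussian(self.exog[~y])
        prior_logit = _rate_logit(self.spike_rate)
        params = bayes_to_stm(mix1, gauss0, prior_logit)
        H = self.history_dim
        if H > 0:
            train = BinnedSpikeTrain(self.endog.astype(int), self.dt)
            isi = estimate_isi([train], H, H * self.dt)
            h = isi_to_history_filter(isi, H)
        else:
            h = np.zeros(0)
        return STMParams(params.A, params.W, params.a, h)

    def fit(self, config: TrainConfig | None = None, val_split=None,
            init: STMParams | None = None, seed: int = 0) -> "EncodingResults":
        if init is None:
            init = self.init_generative(seed=seed)
        return self._wrap(finetune(init, self._design(), self.endog, config,
                                   val_split))


class FactoredSTM(BernoulliEncodingModel):
    """Low-rank STM with shared quadratic features, trained
    discriminatively from a random initialization."""

    family = "fstm"

    def __init__(self, spikes, stimulus=None, history=None, dt=None,
                 n_components: int = 3, n_features: int = 5):
        super().__init__(spikes, stimulus, history, dt)
        self.n_components = n_components
        self.n_features = n_features

    def fit(self, config: TrainConfig | None = None, val_split=None,
            seed: int | None = None) -> "EncodingResults":
        return self._wrap(fit_factored_stm(
            self._design(), self.endog, self.n_components, self.n_features,
            config, val_split, seed=seed))


def _rate_logit(rate):
    p = min(max(rate, 1e-9), 1 - 1e-9)
    return float(np.log(p / (1 - p)))


class EncodingResults:
    """Fit outcome: parameters, training diagnostics, evaluation helpers."""

    def __init__(self, model: BernoulliEncodingModel, fit_result: FitResult):
        self.model = model
        self.fit_result = fit_result
        self.params = fit_result.params

    # -- diagnostics ------------------------------------------------------
    @property
    def train_curve(self):
        """Objective per optimizer iteration, bits/bin."""
        return self.fit_result.train_curve

    @property
    def stopped_early(self):
        return self.fit_result.stopped_early

    @property
    def n_params(self) -> int:
        p = self.params
        base = getattr(p, "base", p)  # flexible-LN models count their filter
        return count_parameters(
            family_of(base), self.model.dim, self.model.history_dim,
            getattr(base, "n_components", 1), getattr(base, "n_features", 0))

    def train_cross_entropy(self) -> float:
        return bernoulli_nll(self.params, self.model._design(),
                             self.model.endog)

    # -- prediction and evaluation ---------------------------------------
    def predict(self, stimulus=None, history=None):
        """Per-bin firing probabilities (training design by default)."""
        if stimulus is None and history is None:
            X, S = self.model._design()
        else:
            X, S = design_arrays((stimulus, history))
        if hasattr(self.params, "firing_prob"):
            return self.params.firing_prob(X, S)
        return firing_prob(self.params, X, S)

    def cross_entropy(self, design, spikes,
                      history_only_report: EvalReport | None = None) -> EvalReport:
        """Held-out cross-entropy report (bits/bin and bits/s)."""
        return _cross_entropy(self.params, design, spikes, self.model.dt,
                              history_only_report)

    def simulate(self, stimulus=None, n_trials: int = 1, seed: int = 0):
        """Sample spike trains from the fitted model with history feedback."""
        X = self.model.exog if stimulus is None else np.atleast_2d(stimulus)
        return [BinnedSpikeTrain(
            sample_from_features(self.params, X, seed=seed + 101 * r),
            self.model.dt, trial_id=r) for r in range(n_trials)]

    def summary(self) -> str:
        p = self.params
        base = getattr(p, "base", p)
        lines = [
            "Bernoulli encoding model fit",
            "=" * 42,
            f"family:            {family_of(base)}"
            + (" (+flexible nonlinearity)" if hasattr(p, "base") else ""),
            f"bins:              {self.model.n_bins}",
            f"bin width:         {self.model.dt * 1e3:.3f} ms",
            f"stimulus dim D:    {self.model.dim}",
            f"history dim H:     {self.model.history_dim}",
            f"parameters:        {self.n_params}",
            f"spike rate:        {self.model.spike_rate / self.model.dt:.2f} Hz",
            f"train CE:          {self.train_cross_entropy():.4f} bits/bin",
            f"early stopping:    {'yes' if self.stopped_early else 'no'}",
        ]
        K = getattr(base, "n_components", None)
        if K is not None:
            lines.insert(3, f"components K:      {K}")
        M = getattr(base, "n_features", None)
        if M is not None:
            lines.insert(4, f"quad features M:   {M}")
        return "\n".join(lines)

    def save(self, path):
        from .io import save_model
        if hasattr(self.params, "base"):
            raise ValueError(
                "flexible-nonlinearity models are not supported by the "
                "model container; save the sigmoid-stage parameters instead")
        return save_model(self.params, path)
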