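"""Generative estimation: spike-triggered distributions and Bayes-rule
conversion into discriminative predictors.

The class-conditional view of a Bernoulli encoding model: the stimulus
features in bins with a spike follow the *spike-triggered* distribution
``p(x | y=1)`` and in bins without one the *non-spike-triggered*
distribution ``p(x | y=0)``.  With mixture-of-Gaussian class conditionals
and a single non-spike-triggered Gaussian, Bayes' rule gives exactly the
STM predictor; with single Gaussians of equal covariance it collapses to a
GLM.  Interspike-interval histograms conditioned on spike/no-spike give the
naive-Bayes history term, an additive log-ratio equal to a linear filter on
the one-hot most-recent-spike vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import multivariate_normal

from .containers import BinnedSpikeTrain
from .params import STMParams, sigmoid

#: relative diagonal jitter used to keep covariances positive definite
COV_JITTER = 1e-6

#: pseudo-count added to every ISI histogram bin before normalization
ISI_PSEUDOCOUNT = 0.5


@dataclass
class GaussianComponent:
    """One mixture component: mean, covariance (symmetric PD) and weight."""

    mean: np.ndarray
    covariance: np.ndarray
    weight: float = 1.0

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.covariance = np.asarray(self.covariance, dtype=float)
        self.covariance = (self.covariance + self.covariance.T) / 2.0
        if self.covariance.shape != (self.mean.size, self.mean.size):
            raise ValueError("covariance must be D x D with D = len(mean)")
        if not 0 < self.weight <= 1:
            raise ValueError("component weight must be in (0, 1]")

    @property
    def dim(self):
        return self.mean.size

    def logpdf(self, x):
        return multivariate_normal.logpdf(x, self.mean, self.covariance,
                                          allow_singular=False)


@dataclass
class MixtureModel:
    """Mixture of Gaussians; weights must sum to 1."""

    components: list[GaussianComponent]

    def __post_init__(self):
        if not self.components:
            raise ValueError("mixture needs at least one component")
        total = sum(c.weight for c in self.components)
        if abs(total - 1.0) > 1e-10:
            raise ValueError(f"mixture weights sum to {total}, expected 1")
        dims = {c.dim for c in self.components}
        if len(dims) > 1:
            raise ValueError("mixture components disagree on dimension")

    @property
    def dim(self):
        return self.components[0].dim

    @property
    def n_components(self):
        return len(self.components)

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        X = np.atleast_2d(x)
        parts = np.stack(
            [np.log(c.weight) + np.atleast_1d(c.logpdf(X)) for c in self.components],
            axis=1,
        )
        out = logsumexp(parts, axis=1)
        return float(out[0]) if single else out

    def log_likelihood(self, samples) -> float:
        """Mean data log-likelihood (nats per sample)."""
        return float(np.mean(self.logpdf(np.atleast_2d(samples))))

    def sample(self, n, rng):
        """Draw n samples; returns (samples, component labels)."""
        weights = np.array([c.weight for c in self.components])
        labels = rng.choice(len(weights), size=n, p=weights)
        out = np.empty((n, self.dim))
        for k, c in enumerate(self.components):
            idx = labels == k
            if idx.any():
                out[idx] = rng.multivariate_normal(c.mean, c.covariance,
                                                   size=int(idx.sum()))
        return out, labels


@dataclass
class ISIHistograms:
    """Histogram estimates of the time-since-last-spike distributions.

    ``g1`` is the distribution at bins containing a spike, ``g0`` at bins
    without one; both share ``bin_edges`` (seconds) and sum to 1.
    ``prior_logit`` is the log-odds of the overall per-bin spike rate.
    """

    bin_edges: np.ndarray
    g1: np.ndarray
    g0: np.ndarray
    prior_logit: float

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.g1 = np.asarray(self.g1, dtype=float)
        self.g0 = np.asarray(self.g0, dtype=float)
        n = self.bin_edges.size - 1
        if self.g1.shape != (n,) or self.g0.shape != (n,):
            raise ValueError("g1/g0 must have one entry per histogram bin")
        for name, g in (("g1", self.g1), ("g0", self.g0)):
            if (g < 0).any():
                raise ValueError(f"{name} has negative mass")
            if abs(g.sum() - 1.0) > 1e-10:
                raise ValueError(f"{name} sums to {g.sum()}, expected 1")

    @property
    def n_bins(self):
        return self.g1.size


def _is_pd(cov):
    try:
        np.linalg.cholesky(cov)
        return True
    except np.linalg.LinAlgError:
        return False


def _jitter_to_pd(cov):
    """Add scaled diagonal jitter until the covariance is positive definite."""
    cov = (cov + cov.T) / 2.0
    if _is_pd(cov):
        return cov
    scale = max(float(np.mean(np.diag(cov))), 1e-12)
    jitter = COV_JITTER * scale
    eye = np.eye(cov.shape[0])
    for _ in range(32):
        if _is_pd(cov + jitter * eye):
            return cov + jitter * eye
        jitter *= 10.0
    raise np.linalg.LinAlgError("could not regularize covariance to PD")


def fit_gaussian(samples) -> GaussianComponent:
    """Maximum-likelihood Gaussian fit (1/N covariance normalization).

    Degenerate sample sets get diagonal jitter instead of failing.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[0] < 2:
        raise ValueError("need at least 2 samples to fit a Gaussian")
    if not np.isfinite(samples).all():
        raise ValueError("samples contain non-finite values")
    mean = samples.mean(axis=0)
    centered = samples - mean
    cov = centered.T @ centered / samples.shape[0]
    cov = _jitter_to_pd(cov)
    return GaussianComponent(mean, cov, 1.0)


def _kmeanspp_centers(samples, K, rng):
    """k-means++ style seeding of K centers from the data."""
    N = samples.shape[0]
    centers = [samples[rng.integers(N)]]
    for _ in range(1, K):
        d2 = np.min(
            [np.sum((samples - c) ** 2, axis=1) for c in centers], axis=0
        )
        total = d2.sum()
        if total <= 0:
            centers.append(samples[rng.integers(N)])
        else:
            centers.append(samples[rng.choice(N, p=d2 / total)])
    return np.array(centers)


def _em_once(samples, K, rng, tol, max_iter):
    """One EM run; returns (mixture, trace of mean log-likelihoods)."""
    N, D = samples.shape
    means = _kmeanspp_centers(samples, K, rng)
    base = fit_gaussian(samples) if N >= 2 else None
    covs = np.array([base.covariance.copy() for _ in range(K)])
    weights = np.full(K, 1.0 / K)
    trace = []
    prev = -np.inf
    for _ in range(max_iter):
        # E-step: log responsibilities
        log_r = np.empty((N, K))
        for k in range(K):
            log_r[:, k] = np.log(weights[k]) + multivariate_normal.logpdf(
                samples, means[k], covs[k], allow_singular=True
            )
        norm = logsumexp(log_r, axis=1)
        trace.append(float(np.mean(norm)))
        r = np.exp(log_r - norm[:, None])
        # M-step
        nk = r.sum(axis=0) + 1e-12
        weights = nk / nk.sum()
        means = (r.T @ samples) / nk[:, None]
        for k in range(K):
            centered = samples - means[k]
            covs[k] = _jitter_to_pd(
                (r[:, k, None] * centered).T @ centered / nk[k]
            )
        if trace[-1] - prev < tol and len(trace) > 1:
            break
        prev = trace[-1]
    weights = weights / weights.sum()
    mix = MixtureModel(
        [GaussianComponent(means[k], covs[k], weights[k]) for k in range(K)]
    )
    return mix, np.array(trace)


def fit_mog_em(samples, K: int, seed=0, n_restarts: int = 5, tol: float = 1e-8,
               max_iter: int = 500):
    """Fit a K-component Gaussian mixture by EM, best of ``n_restarts``.

    The per-iteration data log-likelihood is non-decreasing within each
    run.  Returns ``(MixtureModel, trace)`` where ``trace`` is the winning
    run's mean log-likelihood per iteration.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if K < 1:
        raise ValueError("K must be >= 1")
    if samples.shape[0] == 0:
        raise ValueError("no samples")
    N, D = samples.shape
    if N <= K * D:
        warnings.warn(
            f"only {N} samples for {K} components in {D} dimensions; "
            "the mixture fit may be degenerate", stacklevel=2,
        )
    if K == 1:
        g = fit_gaussian(samples)
        mix = MixtureModel([g])
        return mix, np.array([mix.log_likelihood(samples)])
    rng = np.random.default_rng(seed)
    best, best_trace, best_ll = None, None, -np.inf
    for _ in range(max(1, n_restarts)):
        mix, trace = _em_once(samples, K, rng, tol, max_iter)
        if trace[-1] > best_ll:
            best, best_trace, best_ll = mix, trace, trace[-1]
    return best, best_trace


def bayes_predictor(mix1: MixtureModel, mix0: MixtureModel, prior_logit: float):
    """Log-posterior-odds predictor from class-conditional mixtures.

    Returns ``f`` with ``f(x) = log p(x|spike) - log p(x|no spike) +
    prior_logit``; ``sigmoid(f(x))`` is the exact posterior spike
    probability of the generative model.
    """
    if mix1.dim != mix0.dim:
        raise ValueError(
            f"mixtures disagree on dimension: {mix1.dim} vs {mix0.dim}"
        )

    def f(x):
        return mix1.logpdf(x) - mix0.logpdf(x) + prior_logit

    return f


def bayes_to_stm(mix1: MixtureModel, gauss0: GaussianComponent,
                 prior_logit: float) -> STMParams:
    """Closed-form conversion of (mixture, Gaussian) class conditionals into
    STM parameters.

    For component k of the spike-triggered mixture:
    ``A_k = inv(S0) - inv(S1k)``, ``w_k = inv(S1k) m1k - inv(S0) m0`` and
    ``a_k`` collects log-weights, log-determinants and Mahalanobis
    constants plus the prior log-odds, so that the STM predictor equals the
    Bayes log-posterior-odds at every x.
    """
    if mix1.dim != gauss0.dim:
        raise ValueError(
            f"mixture dimension {mix1.dim} != Gaussian dimension {gauss0.dim}"
        )
    try:
        P0 = np.linalg.inv(gauss0.covariance)
        sign0, logdet0 = np.linalg.slogdet(gauss0.covariance)
        if sign0 <= 0:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "non-spike-triggered covariance is singular; add diagonal jitter"
        ) from None
    m0 = gauss0.mean
    A, W, a = [], [], []
    for c in mix1.components:
        try:
            P1 = np.linalg.inv(c.covariance)
            sign1, logdet1 = np.linalg.slogdet(c.covariance)
            if sign1 <= 0:
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                "spike-triggered component covariance is singular; "
                "add diagonal jitter"
            ) from None
        A.append(P0 - P1)
        W.append(P1 @ c.mean - P0 @ m0)
        a.append(
            np.log(c.weight)
            - 0.5 * logdet1 + 0.5 * logdet0
            - 0.5 * c.mean @ P1 @ c.mean + 0.5 * m0 @ P0 @ m0
            + prior_logit
        )
    # history filter empty: the Bayes stimulus predictor carries no history
    return STMParams(np.array(A), np.array(W), np.array(a), np.zeros(0))


def time_since_last_spike(counts):
    """Per-bin age (in bins) of the most recent *previous* spike.

    Entry t is the number of bins between bin t and the latest spike in
    bins < t (1 = immediately preceding bin); -1 where no spike occurred
    yet.
    """
    counts = np.asarray(counts)
    T = counts.size
    ages = np.full(T, -1, dtype=np.int64)
    last = -1
    for t in range(T):
        if last >= 0:
            ages[t] = t - last
        if counts[t]:
            last = t
    return ages


def estimate_isi(spike_trains, n_bins: int, window: float) -> ISIHistograms:
    """Histogram the time since the last spike, conditioned on spiking.

    ``g1`` uses bins that contain a spike, ``g0`` bins that do not; both
    are restricted to ages within ``window`` seconds, floored with a
    pseudo-count before normalization.  ``prior_logit`` is the logit of the
    overall spike frequency per bin.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    trains = ([spike_trains] if isinstance(spike_trains, BinnedSpikeTrain)
              else list(spike_trains))
    total_spikes = sum(tr.n_spikes for tr in trains)
    if total_spikes == 0:
        raise ValueError("no spikes in any train; cannot estimate ISIs")
    dt = trains[0].dt
    edges = np.linspace(0.0, window, n_bins + 1)
    counts1 = np.zeros(n_bins)
    counts0 = np.zeros(n_bins)
    total_bins = 0
    for tr in trains:
        ages = time_since_last_spike(tr.counts)
        total_bins += len(tr)
        valid = ages > 0
        ages_s = ages[valid] * dt
        spikes = tr.counts[valid].astype(bool)
        inside = ages_s <= window + 1e-12
        # an age of j bins lands in histogram bin floor((j*dt - eps)/bin_width)
        idx = np.minimum(((ages_s[inside] - 1e-12) / (window / n_bins)).astype(int),
                         n_bins - 1)
        np.add.at(counts1, idx[spikes[inside]], 1)
        np.add.at(counts0, idx[~spikes[inside]], 1)
    g1 = counts1 + ISI_PSEUDOCOUNT
    g0 = counts0 + ISI_PSEUDOCOUNT
    g1 /= g1.sum()
    g0 /= g0.sum()
    p = total_spikes / total_bins
    p = min(max(p, 1e-12), 1 - 1e-12)
    return ISIHistograms(edges, g1, g0, float(np.log(p / (1 - p))))


def isi_to_history_filter(isi: ISIHistograms, H: int):
    """History filter ``h_j = log g1(bin j) - log g0(bin j)``.

    Applied to a one-hot most-recent-spike vector this reproduces the
    naive-Bayes interval log-ratio; the pseudo-count floor in
    :func:`estimate_isi` keeps every entry finite.
    """
    if H != isi.n_bins:
        raise ValueError(
            f"history dimension {H} != number of ISI bins {isi.n_bins}"
        )
    return np.log(isi.g1) - np.log(isi.g0)
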