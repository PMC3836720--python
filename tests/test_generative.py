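"""Generative estimation: Gaussian/mixture fits, Bayes conversion, ISIs."""

import numpy as np
import pytest

import spikemix as sm
from spikemix.generative import GaussianComponent, MixtureModel


def two_gaussian_setup(rng, D=3):
    mix1 = MixtureModel([
        GaussianComponent(rng.normal(size=D), _rand_cov(rng, D), 0.4),
        GaussianComponent(rng.normal(size=D), _rand_cov(rng, D), 0.6),
    ])
    gauss0 = GaussianComponent(rng.normal(size=D) * 0.5, _rand_cov(rng, D))
    return mix1, gauss0


def _rand_cov(rng, D):
    R = rng.normal(size=(D, D))
    return R @ R.T / D + np.eye(D)


class TestFitGaussian:
    def test_midpoint_mean(self):
        g = sm.fit_gaussian(np.array([[0.0, 0.0], [2.0, 0.0]]))
        np.testing.assert_allclose(g.mean, [1.0, 0.0])

    def test_monte_carlo_recovery(self, rng):
        samples = rng.multivariate_normal([1.0, -1.0], np.eye(2), 50_000)
        g = sm.fit_gaussian(samples)
        # 3 standard errors of the mean at N = 50k
        np.testing.assert_allclose(g.mean, [1.0, -1.0], atol=0.02)
        np.testing.assert_allclose(g.covariance, np.eye(2), atol=0.05)

    def test_degenerate_points_get_jitter(self):
        g = sm.fit_gaussian(np.ones((10, 3)))
        np.linalg.cholesky(g.covariance)  # PD, not a failure

    def test_too_few_or_nonfinite_samples(self):
        with pytest.raises(ValueError):
            sm.fit_gaussian(np.ones((1, 2)))
        with pytest.raises(ValueError):
            sm.fit_gaussian(np.array([[0.0, np.nan], [1.0, 2.0]]))


class TestMixtureEM:
    def test_k1_equals_single_gaussian(self, rng):
        samples = rng.normal(size=(500, 2))
        mix, _ = sm.fit_mog_em(samples, 1)
        g = sm.fit_gaussian(samples)
        np.testing.assert_array_equal(mix.components[0].mean, g.mean)
        np.testing.assert_array_equal(mix.components[0].covariance,
                                      g.covariance)

    def test_two_cluster_recovery(self, rng):
        pts = np.vstack([rng.normal([-5, 0], 1.0, (1000, 2)),
                         rng.normal([5, 0], 1.0, (1000, 2))])
        mix, _ = sm.fit_mog_em(pts, 2, seed=0)
        means = sorted(c.mean[0] for c in mix.components)
        assert abs(means[0] + 5) < 0.2 and abs(means[1] - 5) < 0.2
        for c in mix.components:
            assert abs(c.weight - 0.5) < 0.05

    def test_em_trace_monotone(self, rng):
        pts = rng.normal(size=(400, 2)) + rng.choice([-3, 3], size=(400, 1))
        _, trace = sm.fit_mog_em(pts, 3, seed=1, n_restarts=2)
        assert np.all(np.diff(trace) >= -1e-8)

    def test_matches_sklearn_likelihood(self, rng):
        """Independent EM cross-check: our best-of-restarts likelihood is
        no worse than scikit-learn's on the same data (both are local
        optimizers of the same objective)."""
        from sklearn.mixture import GaussianMixture
        pts = np.vstack([rng.normal([-4, 1], 1.0, (600, 2)),
                         rng.normal([4, -1], 1.5, (600, 2))])
        mix, _ = sm.fit_mog_em(pts, 2, seed=0)
        ref = GaussianMixture(2, covariance_type="full", n_init=3,
                              random_state=0).fit(pts)
        assert mix.log_likelihood(pts) >= ref.score(pts) - 1e-3

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            sm.fit_mog_em(np.empty((0, 2)), 2)
        with pytest.raises(ValueError):
            sm.fit_mog_em(np.ones((10, 2)), 0)


class TestBayesPredictor:
    def test_identical_mixtures_give_prior(self, rng):
        mix, _ = two_gaussian_setup(rng)
        f = sm.bayes_predictor(mix, mix, prior_logit=-1.2)
        X = rng.normal(size=(50, 3))
        np.testing.assert_allclose(f(X), -1.2, atol=1e-12)

    def test_equal_covariance_is_affine(self, rng):
        """With shared covariance, the log-odds is affine: a regression
        with quadratic features finds no quadratic coefficient."""
        cov = _rand_cov(rng, 2)
        mix1 = MixtureModel([GaussianComponent([1.0, 0.0], cov)])
        mix0 = MixtureModel([GaussianComponent([0.0, 0.5], cov)])
        f = sm.bayes_predictor(mix1, mix0, 0.0)
        g = np.linspace(-2, 2, 11)
        xx, yy = np.meshgrid(g, g)
        X = np.column_stack([xx.ravel(), yy.ravel()])
        vals = f(X)
        design = np.column_stack([X ** 2, X[:, :1] * X[:, 1:], X,
                                  np.ones(len(X))])
        coef, *_ = np.linalg.lstsq(design, vals, rcond=None)
        assert np.abs(coef[:3]).max() < 1e-10

    def test_matches_brute_force_posterior(self, rng):
        mix1, g0 = two_gaussian_setup(rng, D=2)
        mix0 = MixtureModel([g0])
        prior = -2.0
        f = sm.bayes_predictor(mix1, mix0, prior)
        g = np.linspace(-3, 3, 20)
        xx, yy = np.meshgrid(g, g)
        X = np.column_stack([xx.ravel(), yy.ravel()])
        # brute-force Bayes posterior from the mixture densities
        pi = sm.sigmoid(prior)
        num = pi * np.exp(mix1.logpdf(X))
        den = num + (1 - pi) * np.exp(mix0.logpdf(X))
        np.testing.assert_allclose(sm.sigmoid(f(X)), num / den, atol=1e-12)

    def test_dimension_mismatch(self, rng):
        mix1, _ = two_gaussian_setup(rng, D=3)
        mix0 = MixtureModel([GaussianComponent([0.0], [[1.0]])])
        with pytest.raises(ValueError):
            sm.bayes_predictor(mix1, mix0, 0.0)


class TestBayesToSTM:
    def test_defining_identity(self, rng):
        mix1, g0 = two_gaussian_setup(rng)
        prior = -1.5
        stm = sm.bayes_to_stm(mix1, g0, prior)
        f = sm.bayes_predictor(mix1, MixtureModel([GaussianComponent(
            g0.mean, g0.covariance)]), prior)
        X = rng.normal(size=(1000, 3))
        np.testing.assert_allclose(
            sm.predictor(stm, X, np.zeros((1000, 0))), f(X), atol=1e-8)

    def test_equal_covariance_vanishing_quadratic(self, rng):
        cov = _rand_cov(rng, 3)
        mix1 = MixtureModel([GaussianComponent(rng.normal(size=3), cov)])
        stm = sm.bayes_to_stm(mix1, GaussianComponent(np.zeros(3), cov), 0.0)
        assert np.abs(stm.A).max() < 1e-10

    def test_density_scale_invariance(self, rng):
        """Multiplying both class densities by a common factor cancels in
        the log-ratio, so the converted predictor is unchanged."""
        mix1, g0 = two_gaussian_setup(rng)
        prior = 0.7
        stm = sm.bayes_to_stm(mix1, g0, prior)
        X = rng.normal(size=(100, 3))
        log_c = np.log(3.7)
        scaled_ratio = ((mix1.logpdf(X) + log_c)
                        - (np.atleast_1d(g0.logpdf(X)) + log_c) + prior)
        np.testing.assert_allclose(
            sm.predictor(stm, X, np.zeros((100, 0))), scaled_ratio,
            atol=1e-9)

    def test_singular_covariance_suggests_jitter(self, rng):
        mix1, _ = two_gaussian_setup(rng)
        bad = GaussianComponent(np.zeros(3), np.eye(3))
        bad.covariance = np.zeros((3, 3))  # bypass validation deliberately
        with pytest.raises(np.linalg.LinAlgError, match="jitter"):
            sm.bayes_to_stm(mix1, bad, 0.0)

    def test_generative_consistency_gap_shrinks(self, rng):
        """Data from a known mixture pair, refit with EM + Bayes rule:
        the held-out cross-entropy gap to the true model shrinks with N
        (median over seeds, two sample sizes)."""
        D = 2
        true_mix1 = MixtureModel([
            GaussianComponent([2.0, 0.0], np.eye(D) * 0.5, 0.5),
            GaussianComponent([-2.0, 1.0], np.eye(D) * 0.8, 0.5)])
        true_g0 = GaussianComponent([0.0, 0.0], np.eye(D))
        prior = float(np.log(0.05 / 0.95))
        gaps = {1000: [], 10000: []}
        x_test, y_test = _sample_joint(true_mix1, true_g0, prior, 20000,
                                       np.random.default_rng(99))
        true_stm = sm.bayes_to_stm(true_mix1, true_g0, prior)
        ce_true = sm.bernoulli_nll(true_stm, (x_test, None), y_test)
        for seed in range(5):
            r = np.random.default_rng(seed)
            for n in gaps:
                x, y = _sample_joint(true_mix1, true_g0, prior, n, r)
                mix1, _ = sm.fit_mog_em(x[y == 1], 2, seed=seed)
                g0 = sm.fit_gaussian(x[y == 0])
                logit = float(np.log(y.mean() / (1 - y.mean())))
                fit = sm.bayes_to_stm(mix1, g0, logit)
                gaps[n].append(
                    sm.bernoulli_nll(fit, (x_test, None), y_test) - ce_true)
        assert np.median(gaps[10000]) <= np.median(gaps[1000]) + 1e-6


def _sample_joint(mix1, g0, prior_logit, n, rng):
    p_spike = sm.sigmoid(prior_logit)
    y = (rng.random(n) < p_spike).astype(int)
    x = np.empty((n, mix1.dim))
    n1 = int(y.sum())
    if n1:
        x[y == 1], _ = mix1.sample(n1, rng)
    if n - n1:
        x[y == 0] = rng.multivariate_normal(g0.mean, g0.covariance, n - n1)
    return x, y.astype(float)


class TestISI:
    def test_periodic_train_concentrates_g1(self):
        c = np.zeros(100, dtype=int)
        c[9::10] = 1  # a spike every 10 bins
        isi = sm.estimate_isi([sm.BinnedSpikeTrain(c, 0.001)], 20, 0.02)
        assert isi.g1.argmax() == 9
        # all true interval mass in one bin; rest is the pseudo-count floor
        assert isi.g1[9] > 10 * np.delete(isi.g1, 9).max()

    def test_histograms_normalized(self, rng):
        c = (rng.random(5000) < 0.03).astype(int)
        isi = sm.estimate_isi([sm.BinnedSpikeTrain(c, 0.001)], 50, 0.05)
        assert isi.g1.sum() == pytest.approx(1.0, abs=1e-10)
        assert isi.g0.sum() == pytest.approx(1.0, abs=1e-10)

    def test_homogeneous_train_equal_conditionals(self):
        rng = np.random.default_rng(5)
        c = (rng.random(100_000) < 0.05).astype(int)
        isi = sm.estimate_isi([sm.BinnedSpikeTrain(c, 0.001)], 30, 0.03)
        tv = 0.5 * np.abs(isi.g1 - isi.g0).sum()
        assert tv < 0.05
        h = sm.isi_to_history_filter(isi, 30)
        assert np.abs(h).max() < 0.5  # history term near zero everywhere

    def test_no_spikes_errors(self):
        with pytest.raises(ValueError):
            sm.estimate_isi([sm.BinnedSpikeTrain(np.zeros(10, int), 0.001)],
                            10, 0.01)


class TestHistoryFilter:
    def test_equal_histograms_zero_filter(self):
        edges = np.linspace(0, 0.01, 11)
        g = np.full(10, 0.1)
        isi = sm.ISIHistograms(edges, g, g, 0.0)
        np.testing.assert_array_equal(sm.isi_to_history_filter(isi, 10),
                                      np.zeros(10))

    def test_filter_equals_log_ratio_per_bin(self, rng):
        g1 = rng.random(10) + 0.1
        g1 /= g1.sum()
        g0 = rng.random(10) + 0.1
        g0 /= g0.sum()
        isi = sm.ISIHistograms(np.linspace(0, 0.01, 11), g1, g0, 0.0)
        h = sm.isi_to_history_filter(isi, 10)
        for j in range(10):
            s = np.zeros(10)
            s[j] = 1.0
            assert sm.history_term(s, h) == pytest.approx(
                np.log(g1[j]) - np.log(g0[j]))

    def test_zero_mass_bin_stays_finite(self):
        c = np.zeros(50, dtype=int)
        c[9::10] = 1
        isi = sm.estimate_isi([sm.BinnedSpikeTrain(c, 0.001)], 20, 0.02)
        h = sm.isi_to_history_filter(isi, 20)
        assert np.isfinite(h).all()

    def test_bin_count_mismatch(self):
        edges = np.linspace(0, 0.01, 11)
        g = np.full(10, 0.1)
        isi = sm.ISIHistograms(edges, g, g, 0.0)
        with pytest.raises(ValueError):
            sm.isi_to_history_filter(isi, 12)
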