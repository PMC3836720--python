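"""Objective, gradients, fine-tuning, pipelines and early stopping."""

import numpy as np
import pytest

import spikemix as sm
from spikemix.training import (nll_and_grad, pack_params, spike_array,
                               unpack_params)

LOG2 = np.log(2.0)


def random_instance(rng, family, D=4, H=6, K=2, M=2, T=200):
    X = rng.normal(size=(T, D))
    S = np.zeros((T, H))
    S[np.arange(T), rng.integers(0, H, T)] = 1.0
    S[rng.random(T) < 0.3] = 0.0  # some bins without history
    y = rng.integers(0, 2, T).astype(float)
    if family == "glm":
        p = sm.GLMParams(rng.normal(size=D), rng.normal(size=H), 0.2)
    elif family == "quadratic":
        A = rng.normal(size=(D, D))
        p = sm.QuadraticParams((A + A.T) / 2, rng.normal(size=D),
                               rng.normal(size=H), 0.2)
    elif family == "stm":
        A = rng.normal(size=(K, D, D))
        p = sm.STMParams((A + A.transpose(0, 2, 1)) / 2,
                         rng.normal(size=(K, D)), rng.normal(size=K),
                         rng.normal(size=H))
    else:
        p = sm.FactoredSTMParams(rng.normal(size=(D, M)),
                                 rng.normal(size=(K, M)),
                                 rng.normal(size=(K, D)),
                                 rng.normal(size=K), rng.normal(size=H))
    return p, X, S, y


def finite_difference(params, X, S, y, step=1e-5):
    x0 = pack_params(params)
    fd = np.empty_like(x0)
    for i in range(x0.size):
        e = np.zeros_like(x0)
        e[i] = step
        fp, _ = nll_and_grad(unpack_params(x0 + e, params), X, S, y)
        fm, _ = nll_and_grad(unpack_params(x0 - e, params), X, S, y)
        fd[i] = (fp - fm) / (2 * step)
    return fd


class TestBernoulliNLL:
    def test_confident_predictions_approach_zero(self):
        y = np.array([1.0, 0.0, 1.0])
        p = sm.GLMParams(np.zeros(1), np.zeros(0), 30.0)
        # predictor 30 -> p ~ 1; evaluate on all-spike data
        assert sm.bernoulli_nll(p, (np.zeros((3, 1)), None),
                                np.ones(3)) < 1e-10

    def test_coin_flip_is_one_bit(self, rng):
        p = sm.GLMParams(np.zeros(2), np.zeros(0), 0.0)
        y = rng.integers(0, 2, 50).astype(float)
        assert sm.bernoulli_nll(p, (np.zeros((50, 2)), None), y) == \
            pytest.approx(1.0)

    def test_two_bin_hand_case(self):
        """y=(1,0), p=(0.8,0.4): CE = -(log2 .8 + log2 .6)/2 = 0.5293."""
        p = sm.GLMParams(np.ones(1), np.zeros(0), 0.0)
        X = np.array([[np.log(0.8 / 0.2)], [np.log(0.4 / 0.6)]])
        y = np.array([1.0, 0.0])
        expected = -0.5 * (np.log2(0.8) + np.log2(0.6))
        assert sm.bernoulli_nll(p, (X, None), y) == pytest.approx(
            expected, abs=1e-10)
        assert expected == pytest.approx(0.5294, abs=5e-5)

    def test_misaligned_inputs_error(self, rng):
        p = sm.GLMParams(np.ones(2), np.zeros(0), 0.0)
        with pytest.raises(ValueError):
            sm.bernoulli_nll(p, (rng.normal(size=(10, 2)), None), np.ones(9))


class TestGradient:
    @pytest.mark.parametrize("family", ["glm", "quadratic", "stm", "fstm"])
    def test_finite_difference_agreement(self, family):
        rng = np.random.default_rng(hash(family) % 2**31)
        params, X, S, y = random_instance(rng, family)
        _, grad = nll_and_grad(params, X, S, y)
        fd = finite_difference(params, X, S, y)
        scale = np.abs(fd) + 1e-8
        assert np.max(np.abs(grad - fd) / scale) < 1e-5

    def test_stationary_at_perfect_predictions(self):
        # p_t == y_t exactly at saturation: gradient vanishes
        p = sm.GLMParams(np.array([30.0]), np.zeros(0), 0.0)
        X = np.array([[1.0], [-1.0]])
        y = np.array([1.0, 0.0])
        g = sm.gradient(p, (X, None), y)
        assert np.linalg.norm(g) < 1e-10

    def test_glm_gradient_closed_form(self, rng):
        params, X, S, y = random_instance(rng, "glm")
        g = sm.gradient(params, (X, S), y)
        p = sm.firing_prob(params, X, S)
        T = y.size
        np.testing.assert_allclose(g[:4], X.T @ (p - y) / T, atol=1e-12)
        np.testing.assert_allclose(g[4:10], S.T @ (p - y) / T, atol=1e-12)
        assert g[-1] == pytest.approx(np.mean(p - y))


class TestFinetune:
    def test_matches_independent_convex_solver(self, rng):
        """Logistic regression is convex: the sigmoid-GLM fit lands on the
        same optimum as an independent solver."""
        import statsmodels.api as smapi
        params, X, S, y = random_instance(rng, "glm", T=2000)
        init = sm.GLMParams(np.zeros(4), np.zeros(6), 0.0)
        res = sm.finetune(init, (X, S), y, sm.TrainConfig(max_iter=500))
        ours = sm.bernoulli_nll(res.params, (X, S), y)
        design = np.column_stack([X, S, np.ones(len(y))])
        ref = smapi.Logit(y, design).fit(disp=0, method="lbfgs", maxiter=500)
        theirs = -ref.llf / len(y) / LOG2
        assert abs(ours - theirs) < 1e-6

    def test_multiple_starts_same_convex_optimum(self, rng):
        params, X, S, y = random_instance(rng, "glm", T=1000)
        vals = []
        for seed in range(3):
            r = np.random.default_rng(seed)
            init = sm.GLMParams(r.normal(size=4), r.normal(size=6),
                                r.normal())
            res = sm.finetune(init, (X, S), y, sm.TrainConfig(max_iter=500))
            vals.append(sm.bernoulli_nll(res.params, (X, S), y))
        assert max(vals) - min(vals) < 1e-6

    def test_zero_iterations_returns_init(self, rng):
        params, X, S, y = random_instance(rng, "glm")
        res = sm.finetune(params, (X, S), y, sm.TrainConfig(max_iter=0))
        np.testing.assert_array_equal(res.params.w, params.w)
        assert not res.stopped_early

    def test_objective_never_worse_than_init(self, rng):
        params, X, S, y = random_instance(rng, "stm", T=500)
        before = sm.bernoulli_nll(params, (X, S), y)
        res = sm.finetune(params, (X, S), y, sm.TrainConfig(max_iter=100))
        assert sm.bernoulli_nll(res.params, (X, S), y) <= before + 1e-12

    def test_nonfinite_init_errors(self, rng):
        params, X, S, y = random_instance(rng, "glm")
        X = X.copy()
        X[0, 0] = 1e300
        bad = sm.GLMParams(np.full(4, 1e10), np.zeros(6), 0.0)
        with pytest.raises(ValueError):
            sm.finetune(bad, (X * np.nan, S), y)

    def test_early_stopping_returns_best_validation(self, rng):
        """With a validation split, the returned parameters achieve the
        minimum validation objective among all checked iterations."""
        params, X, S, y = random_instance(rng, "stm", T=2000)
        _, Xv, Sv, yv = random_instance(rng, "stm", T=500)
        cfg = sm.TrainConfig(max_iter=200, check_every=2, patience=3)
        init, *_ = random_instance(np.random.default_rng(0), "stm")
        res = sm.finetune(init, (X, S), y, cfg,
                          val_split=((Xv, Sv), yv))
        val_final = sm.bernoulli_nll(res.params, (Xv, Sv), yv)
        # re-running without validation and evaluating cannot beat it at
        # any multiple-of-check_every snapshot; sanity: final <= init val
        val_init = sm.bernoulli_nll(init, (Xv, Sv), yv)
        assert val_final <= val_init + 1e-12


class TestSTMRecovery:
    def test_data_efficiency_monotone(self):
        """Median held-out cross-entropy is non-increasing in training-set
        size (1k, 5k, 20k bins) for the factored STM."""
        sizes = [1000, 5000, 20000]
        medians = {}
        ce = {n: [] for n in sizes}
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            truth = sm.FactoredSTMParams(
                rng.normal(size=(4, 2)), rng.normal(size=(2, 2)),
                0.5 * rng.normal(size=(2, 4)), [-4.0, -4.5], np.zeros(0))
            Xall = rng.normal(size=(25000, 4))
            yall = sm.sample_from_features(truth, Xall, seed=seed)
            Xte = rng.normal(size=(20000, 4))
            yte = sm.sample_from_features(truth, Xte, seed=seed + 50)
            for n in sizes:
                res = sm.fit_factored_stm(
                    (Xall[:n], None), yall[:n], K=2, M=2,
                    config=sm.TrainConfig(max_iter=300), seed=seed)
                ce[n].append(sm.bernoulli_nll(res.params, (Xte, None), yte))
        medians = {n: np.median(ce[n]) for n in sizes}
        assert medians[5000] <= medians[1000] + 1e-9
        assert medians[20000] <= medians[5000] + 1e-9


class TestGLMPipeline:
    @pytest.fixture(scope="class")
    def v_shaped_data(self):
        rng = np.random.default_rng(0)
        T = 30000
        X = rng.normal(size=(T, 3))
        w = np.array([1.0, 0.5, -0.5])
        p = np.clip(0.4 * np.abs(np.tanh(X @ w)), 1e-6, 1 - 1e-6)
        y = (rng.random(T) < p).astype(float)
        return X, y

    def test_well_specified_sigmoid_stages_do_not_help(self, rng):
        T = 30000
        X = rng.normal(size=(T, 3))
        w = np.array([1.0, 0.5, -0.5])
        y = (rng.random(T) < sm.sigmoid(X @ w - 2.0)).astype(float)
        val = ((X[20000:], None), y[20000:])
        cfg = sm.TrainConfig(max_iter=200)
        pipe = sm.fit_glm_pipeline((X[:20000], None), y[:20000], "linear",
                                   cfg, val_split=val)
        base = sm.finetune(sm.GLMParams(np.zeros(3), np.zeros(0), -2.0),
                           (X[:20000], None), y[:20000], cfg)
        ce_pipe = sm.bernoulli_nll(pipe.params, *val)
        ce_sig = sm.bernoulli_nll(base.params, *val)
        assert ce_pipe <= ce_sig + 1e-3          # guard: never degrades
        assert ce_sig - ce_pipe < 0.01           # and cannot help much

    def test_sign_invariant_neuron_needs_flexible_stage(self, v_shaped_data):
        """A V-shaped (sign-invariant) nonlinearity is invisible to the
        sigmoid stage; the flexible stages capture it."""
        X, y = v_shaped_data
        val = ((X[20000:], None), y[20000:])
        cfg = sm.TrainConfig(max_iter=200)
        pipe = sm.fit_glm_pipeline((X[:20000], None), y[:20000], "linear",
                                   cfg, val_split=val)
        base = sm.finetune(sm.GLMParams(np.zeros(3), np.zeros(0), -1.0),
                           (X[:20000], None), y[:20000], cfg)
        ce_pipe = sm.bernoulli_nll(pipe.params, *val)
        ce_sig = sm.bernoulli_nll(base.params, *val)
        assert ce_pipe < ce_sig - 0.01
        assert isinstance(pipe.params, sm.FlexibleLNParams)

    def test_histogram_reproduces_training_frequencies(self, rng):
        from spikemix.training import HistogramNonlinearity
        z = rng.normal(size=5000)
        y = (rng.random(5000) < sm.sigmoid(2 * z)).astype(float)
        hist = HistogramNonlinearity.fit(z, y, n_bins=150)
        idx = np.clip(np.searchsorted(hist.bin_edges, z, side="right") - 1,
                      0, 149)
        for j in np.unique(idx):
            sel = idx == j
            assert hist.probs[j] == pytest.approx(y[sel].mean())

    def test_blob_nonlinearity_bounded(self, rng):
        nl = sm.BlobNonlinearity(rng.normal(size=5), rng.normal(size=5),
                                 rng.normal(size=5))
        out = nl(rng.normal(size=1000) * 10)
        assert np.all(out >= 0) and np.all(out < 1)


class TestFactoredSTMFit:
    def test_m0_k1_reduces_to_glm(self, rng):
        params, X, S, y = random_instance(rng, "glm", T=3000)
        y = (rng.random(3000) < sm.firing_prob(params, X, S)).astype(float)
        cfg = sm.TrainConfig(max_iter=400)
        res_f = sm.fit_factored_stm((X, S), y, K=1, M=0, config=cfg)
        init = sm.GLMParams(np.zeros(4), np.zeros(6), 0.0)
        res_g = sm.finetune(init, (X, S), y, cfg)
        assert abs(sm.bernoulli_nll(res_f.params, (X, S), y)
                   - sm.bernoulli_nll(res_g.params, (X, S), y)) < 1e-4

    def test_stable_across_seeds(self):
        r = np.random.default_rng(2024)
        truth = sm.FactoredSTMParams(
            r.normal(size=(4, 2)), np.abs(r.normal(size=(2, 2))),
            0.5 * r.normal(size=(2, 4)), [-3.5, -4.0], np.zeros(0))
        X = r.normal(size=(20000, 4))
        y = sm.sample_from_features(truth, X, seed=0)
        Xte = r.normal(size=(10000, 4))
        yte = sm.sample_from_features(truth, Xte, seed=1)
        ces = []
        for seed in range(5):
            res = sm.fit_factored_stm((X, None), y, K=2, M=2,
                                      config=sm.TrainConfig(max_iter=300),
                                      seed=seed)
            ces.append(sm.bernoulli_nll(res.params, (Xte, None), yte))
        assert max(ces) - min(ces) < 0.03

    def test_optimized_entry_count_matches_bookkeeping(self, rng):
        from spikemix.training import random_factored_init
        init = random_factored_init(D=10, H=100, K=6, M=5, spike_rate=0.01)
        assert pack_params(init).size == sm.count_parameters(
            "fstm", 10, 100, 6, 5) == 246
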