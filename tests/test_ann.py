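"""Feedforward nets, Bayesian-regularized Levenberg-Marquardt, splits."""

import numpy as np
import pytest

from sheepvitals.ann import (BRNetClassifier, BRNetRegressor, FFNet,
                             TrainConfig, _jacobian, forward, predict_class,
                             predict_values, split,
                             train_bayesian_regularization)


class TestSplit:
    @pytest.mark.parametrize("n,n_train,n_test", [(134, 94, 40), (10, 7, 3)])
    def test_70_30_counts(self, n, n_train, n_test):
        ds = split(n, seed=1)
        assert len(ds.train_idx) == n_train
        assert len(ds.test_idx) == n_test
        assert set(ds.train_idx) | set(ds.test_idx) == set(range(n))
        assert not set(ds.train_idx) & set(ds.test_idx)

    def test_deterministic_given_seed(self):
        a, b = split(50, seed=7), split(50, seed=7)
        assert (a.train_idx == b.train_idx).all()
        assert not (split(50, seed=8).train_idx == a.train_idx).all()


class TestForward:
    def test_zero_weights_linear_returns_bias(self):
        net = FFNet(w1=np.zeros((3, 2)), b1=np.zeros(3),
                    w2=np.zeros((1, 3)), b2=np.array([2.5]))
        out = forward(net, np.random.default_rng(0).normal(size=(5, 2)))
        assert np.allclose(out, 2.5)

    def test_zero_weights_softmax_uniform(self):
        net = FFNet(w1=np.zeros((4, 2)), b1=np.zeros(4),
                    w2=np.zeros((3, 4)), b2=np.zeros(3), out_act="softmax")
        out = forward(net, np.zeros((2, 2)))
        assert np.allclose(out, 1 / 3)
        assert np.allclose(out.sum(axis=1), 1.0)

    def test_hand_computed_single_hidden_unit(self):
        net = FFNet(w1=np.array([[0.5, -0.25]]), b1=np.array([0.1]),
                    w2=np.array([[2.0]]), b2=np.array([-0.3]))
        x = np.array([[1.0, 2.0]])
        expected = 2.0 * np.tanh(0.5 - 0.5 + 0.1) - 0.3
        assert forward(net, x)[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        net = FFNet.init(3, 4, 1)
        with pytest.raises(ValueError, match="columns"):
            forward(net, np.zeros((2, 5)))


class TestJacobian:
    def test_matches_central_finite_differences(self):
        net = FFNet.init(2, 1, 1, rng=np.random.default_rng(1))
        X = np.random.default_rng(2).normal(size=(6, 2))
        J, _ = _jacobian(net, X)
        w0 = net.get_flat()
        eps = 1e-6
        J_fd = np.zeros_like(J)
        for i in range(w0.size):
            for sgn, buf in ((1, "p"), (-1, "m")):
                w = w0.copy()
                w[i] += sgn * eps
                net.set_flat(w)
                z = forward(net, X, linear=True).ravel()
                if sgn == 1:
                    zp = z
                else:
                    J_fd[:, i] = (zp - z) / (2 * eps)
        net.set_flat(w0)
        assert np.abs(J - J_fd).max() < 1e-6 * max(1.0, np.abs(J_fd).max())


class TestTraining:
    def test_noise_free_linear_map_fit_to_machine_precision(self):
        X = np.linspace(-1, 1, 20)[:, None]
        Y = 2.0 * X
        net = FFNet.init(1, 10, 1, rng=np.random.default_rng(0))
        trace = train_bayesian_regularization(net, X, Y)
        assert np.mean((forward(net, X) - Y) ** 2) < 1e-6
        assert trace[-1].gamma < 0.5 * net.n_params

    def test_xor_classified_across_seeds(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], float) * 2 - 1
        y = np.array([0, 1, 1, 0])
        for seed in range(5):
            clf = BRNetClassifier(n_hidden=10, max_epochs=200,
                                  random_state=seed)
            clf.fit(X, y)
            assert (clf.predict(X) == y).all(), f"seed {seed}"

    def test_objective_monotone_over_accepted_steps(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 3))
        Y = np.sin(X.sum(axis=1, keepdims=True)) + rng.normal(0, 0.1, (30, 1))
        net = FFNet.init(3, 6, 1, rng=rng)
        trace = train_bayesian_regularization(net, X, Y)
        assert all(s.f_after <= s.f_before for s in trace)
        assert all(s.alpha > 0 or s.epoch <= 5 for s in trace)

    def test_regularization_suppresses_pure_noise_fit(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(-1, 1, (30, 2))
        Y = rng.normal(0, 1, (30, 1))
        def run(bayes):
            net = FFNet.init(2, 10, 1, rng=np.random.default_rng(7))
            tr = train_bayesian_regularization(
                net, X, Y, TrainConfig(max_epochs=300, bayes=bayes))
            return tr[-1]
        br, lm = run(True), run(False)
        assert br.sse_weights < lm.sse_weights
        assert br.gamma < net_params_of(2, 10, 1)

    def test_bayes_generalizes_at_least_as_well_as_plain_lm(self):
        results = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.uniform(-1, 1, (40, 1))
            Y = np.sin(2 * X) + rng.normal(0, 0.3, (40, 1))
            Xt = rng.uniform(-1, 1, (200, 1))
            Yt = np.sin(2 * Xt)
            row = []
            for bayes in (True, False):
                net = FFNet.init(1, 10, 1, rng=np.random.default_rng(seed + 100))
                train_bayesian_regularization(
                    net, X, Y, TrainConfig(max_epochs=300, bayes=bayes))
                row.append(float(np.mean((forward(net, Xt) - Yt) ** 2)))
            results.append(row)
        results = np.asarray(results)
        assert np.median(results[:, 0]) <= np.median(results[:, 1])

    def test_train_mse_below_test_mse_on_noisy_task(self):
        # regularization keeps the gap small, so compare medians over
        # several seeds rather than a single draw
        gaps = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.uniform(-1, 1, (60, 2))
            Y = (X[:, :1] ** 2 - X[:, 1:]) + rng.normal(0, 0.2, (60, 1))
            ds = split(60, seed=seed)
            reg = BRNetRegressor(n_hidden=10, random_state=seed)
            reg.fit(X[ds.train_idx], Y[ds.train_idx])
            mse = lambda idx: float(np.mean((reg.predict(X[idx]) - Y[idx]) ** 2))
            gaps.append(mse(ds.test_idx) - mse(ds.train_idx))
        assert np.median(gaps) > 0


def net_params_of(ni, nh, no):
    return nh * ni + nh + no * nh + no


class TestPredictHelpers:
    def test_scores_are_probabilities(self):
        net = FFNet.init(4, 5, 3, out_act="softmax",
                         rng=np.random.default_rng(0))
        labels, scores = predict_class(net, np.random.default_rng(1).normal(size=(7, 4)))
        assert scores.shape == (7, 3)
        assert np.allclose(scores.sum(axis=1), 1.0)
        assert ((scores >= 0) & (scores <= 1)).all()
        assert (labels == scores.argmax(axis=1)).all()

    def test_values_finite_and_deterministic(self):
        net = FFNet.init(3, 5, 2, rng=np.random.default_rng(0))
        X = np.random.default_rng(2).normal(size=(5, 3))
        a, b = predict_values(net, X), predict_values(net, X)
        assert np.isfinite(a).all()
        np.testing.assert_array_equal(a, b)


class TestEstimatorAPI:
    def test_get_set_params_clone(self):
        from sklearn.base import clone
        clf = BRNetClassifier(n_hidden=7, max_epochs=50, random_state=3)
        c2 = clone(clf)
        assert c2.get_params() == clf.get_params()

    def test_regressor_standardizes_targets(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(-1, 1, (40, 2))
        Y = 100 + 50 * X[:, 0]
        reg = BRNetRegressor(random_state=0)
        reg.fit(X, Y)
        pred = reg.predict(X)
        assert pred.shape == (40,)
        assert np.corrcoef(pred, Y)[0, 1] > 0.99
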