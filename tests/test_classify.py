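"""LSTM cell mechanics, BPTT gradients, training behavior, and the RBF-SVM."""

import numpy as np
import pytest

from squatstab.classify import (LSTMClassifier, LSTMParams, LSTMState,
                                TrainConfig, _loss_and_grads, lstm_cell_step,
                                lstm_forward, predict, train_lstm, train_svm)
from squatstab.errors import FeatureSetMismatchError, ParameterError
from squatstab.features import LabeledDataset


def _state(h, k=1, H=0.0, C=0.0):
    return LSTMState(H=np.full((k, h), H, dtype=float),
                     C=np.full((k, h), C, dtype=float))


def _dataset(X, y):
    return LabeledDataset(X=X, y=np.asarray(y, dtype=int),
                          subjects=np.zeros(len(y)),
                          feature_ids=tuple(range(1, X.shape[2] + 1)))


def _toy_problem(n=200, seed=7):
    """Separable sequence task: class = mean of channel 1 above channel 2."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(0, 1, (n, 20, 2))
    y = (X[:, :, 0].mean(axis=1) > X[:, :, 1].mean(axis=1)).astype(int)
    return _dataset(X, y)


class TestCellStep:
    def test_zero_weights_hand_evaluation(self):
        # all gates sigmoid(0)=0.5, input node tanh(0)=0:
        # C_t = 0.5 c, H_t = 0.5 tanh(0.5 c)
        params = LSTMParams.zeros(m=3, h=4)
        c = 0.8
        out = lstm_cell_step(np.ones((1, 3)), _state(4, C=c), params)
        np.testing.assert_allclose(out.C, 0.5 * c, rtol=1e-12)
        np.testing.assert_allclose(out.H, 0.5 * np.tanh(0.5 * c), rtol=1e-12)

    def test_open_forget_closed_input_preserves_cell_exactly(self):
        params = LSTMParams.zeros(m=2, h=3)
        params.b_f[:] = 50.0   # forget gate -> 1 exactly in float64
        params.b_i[:] = -50.0  # input gate -> 0 exactly
        C_prev = np.array([[0.3, -1.2, 4.5]])
        out = lstm_cell_step(np.ones((1, 2)), LSTMState(H=np.zeros((1, 3)),
                                                        C=C_prev), params)
        np.testing.assert_array_equal(out.C, C_prev)

    def test_closed_output_gate_silences_hidden_state(self):
        params = LSTMParams.zeros(m=2, h=3)
        params.b_o[:] = -50.0
        out = lstm_cell_step(np.ones((1, 2)), _state(3, C=2.0), params)
        np.testing.assert_array_equal(out.H, 0.0)

    def test_shape_mismatch_rejected(self):
        params = LSTMParams.zeros(m=3, h=2)
        with pytest.raises(ParameterError):
            lstm_cell_step(np.ones((1, 5)), _state(2), params)

    def test_gate_ranges_over_random_sweep(self):
        """Gates stay in (0,1) and |H| < 1 for 10^4 random parameter/input draws."""
        rng = np.random.default_rng(0)
        n = 10_000
        m, h = 3, 2
        U = rng.normal(0, 3, (n, m))
        H = rng.uniform(-0.999, 0.999, (n, h))
        C = rng.normal(0, 3, (n, h))
        for _ in range(3):  # a few random parameter draws over the same batch
            params = LSTMParams.init(m, h, rng)
            for arr in (params.W_ui, params.W_uf, params.W_uo, params.W_uc):
                arr *= rng.uniform(0.5, 10)
            out = lstm_cell_step(U, LSTMState(H=H, C=C), params)
            assert np.all(np.abs(out.H) < 1.0)
            assert np.isfinite(out.C).all()


class TestForward:
    def test_softmax_outputs_sum_to_one(self, rng):
        params = LSTMParams.init(4, 8, rng)
        X = rng.normal(size=(6, 20, 4))
        scores, logits = lstm_forward(X, params)
        probs = np.exp(logits - logits.max(axis=1, keepdims=True))
        probs /= probs.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, rtol=1e-12)
        np.testing.assert_allclose(scores, probs[:, 1], rtol=1e-12)

    def test_zero_weight_network_scores_half(self):
        params = LSTMParams.zeros(m=5, h=4)
        score, _ = lstm_forward(np.random.default_rng(1).normal(size=(20, 5)), params)
        assert score == pytest.approx(0.5)

    def test_unroll_equals_manual_cell_steps(self, rng):
        params = LSTMParams.init(3, 5, rng)
        seq = rng.normal(size=(20, 3))
        state = LSTMState(H=np.zeros((1, 5)), C=np.zeros((1, 5)))
        for t in range(20):
            state = lstm_cell_step(seq[t:t + 1], state, params)
        logits_manual = (state.H @ params.W_fc + params.b_fc)[0]
        _, logits = lstm_forward(seq, params)
        np.testing.assert_allclose(logits, logits_manual, rtol=1e-12)

    def test_wrong_sequence_length_rejected(self, rng):
        params = LSTMParams.init(3, 4, rng)
        with pytest.raises(ParameterError):
            lstm_forward(rng.normal(size=(7, 19, 3)), params)


class TestGradients:
    def test_bptt_matches_numerical_gradient(self):
        """Analytic BPTT gradients agree with central differences to 1e-5."""
        rng = np.random.default_rng(3)
        params = LSTMParams.init(m=3, h=2, rng=rng)
        X = rng.normal(size=(4, 6, 3))
        y = np.array([0, 1, 1, 0])
        _, grads = _loss_and_grads(params, X, y)
        eps = 1e-6
        for name in params.names():
            W = getattr(params, name)
            G = getattr(grads, name)
            it = np.nditer(W, flags=["multi_index"])
            for _ in it:
                ix = it.multi_index
                orig = W[ix]
                W[ix] = orig + eps
                lp, _ = _loss_and_grads(params, X, y)
                W[ix] = orig - eps
                lm, _ = _loss_and_grads(params, X, y)
                W[ix] = orig
                num = (lp - lm) / (2 * eps)
                denom = max(abs(num), abs(G[ix]), 1e-8)
                assert abs(G[ix] - num) / denom < 1e-5, (name, ix)


class TestTrainLSTM:
    def test_separable_toy_reaches_high_training_accuracy(self):
        ds = _toy_problem()
        model = train_lstm(ds, TrainConfig(hidden=16, epochs=150, seed=3))
        _, pred = predict(model, ds)
        assert (pred == ds.y).mean() >= 0.95

    def test_smoothed_loss_trace_decreases(self):
        ds = _toy_problem()
        model = train_lstm(ds, TrainConfig(hidden=16, epochs=60, seed=3))
        w = 10
        smooth = np.convolve(model.loss_trace, np.ones(w) / w, mode="valid")
        assert smooth[-1] < smooth[0]

    def test_same_seed_reproduces_final_loss(self):
        ds = _toy_problem(n=80)
        cfg = TrainConfig(hidden=8, epochs=10, seed=5)
        a = train_lstm(ds, cfg)
        b = train_lstm(ds, cfg)
        assert a.loss_trace[-1] == b.loss_trace[-1]

    def test_single_class_rejected(self):
        ds = _dataset(np.zeros((10, 20, 2)), np.zeros(10))
        with pytest.raises(ParameterError):
            train_lstm(ds, TrainConfig(epochs=1))


def _blobs(n_per=40, d=6, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(-2, 0.3, (n_per, 20, d // 2)).reshape(n_per, 20, -1),
                   rng.normal(2, 0.3, (n_per, 20, d // 2)).reshape(n_per, 20, -1)])
    y = np.array([0] * n_per + [1] * n_per)
    return _dataset(X, y)


class TestTrainSVM:
    def test_separable_blobs_perfect_training_accuracy(self):
        ds = _blobs()
        model = train_svm(ds, TrainConfig(seed=0))
        _, pred = predict(model, ds)
        assert (pred == ds.y).all()
        assert np.abs(model.dual_coef).max() <= model.C + 1e-9
        assert model.support_vectors.shape[0] >= 1

    def test_duplicating_training_points_leaves_decision_unchanged(self, rng):
        ds = _blobs()
        doubled = _dataset(np.concatenate([ds.X, ds.X]),
                           np.concatenate([ds.y, ds.y]))
        a = train_svm(ds, TrainConfig(seed=0))
        b = train_svm(doubled, TrainConfig(seed=0))
        probe = rng.normal(0, 2, (30, ds.X.shape[1] * ds.X.shape[2]))
        np.testing.assert_allclose(a.svc.decision_function(probe),
                                   b.svc.decision_function(probe), atol=1e-6)

    def test_training_order_permutation_invariance(self, rng):
        ds = _blobs()
        perm = rng.permutation(ds.n)
        a = train_svm(ds, TrainConfig(seed=0))
        b = train_svm(_dataset(ds.X[perm], ds.y[perm]), TrainConfig(seed=0))
        probe = rng.normal(0, 2, (30, ds.X.shape[1] * ds.X.shape[2]))
        np.testing.assert_allclose(a.svc.decision_function(probe),
                                   b.svc.decision_function(probe), atol=1e-2)

    def test_vanishing_gamma_flattens_decision_scores(self, rng):
        ds = _blobs()
        model = train_svm(ds, TrainConfig(seed=0, svm_gamma=1e-9))
        probe = rng.normal(0, 2, (40, ds.X.shape[1] * ds.X.shape[2]))
        assert model.svc.decision_function(probe).std() < 1e-3

    def test_single_class_rejected(self):
        ds = _dataset(np.zeros((10, 20, 2)), np.ones(10))
        with pytest.raises(ParameterError):
            train_svm(ds, TrainConfig())


class TestPredict:
    def test_feature_set_mismatch_names_expected_ids(self):
        ds = _toy_problem(n=60)
        model = train_lstm(ds, TrainConfig(hidden=4, epochs=2, seed=0))
        other = _dataset(ds.X[:, :, :1], ds.y)
        with pytest.raises(FeatureSetMismatchError, match=r"\(1, 2\)"):
            predict(model, other)

    def test_permuting_squats_permutes_outputs(self, rng):
        ds = _toy_problem(n=60)
        for trainer in (lambda d: train_lstm(d, TrainConfig(hidden=4, epochs=3, seed=0)),
                        lambda d: train_svm(d, TrainConfig(seed=0))):
            model = trainer(ds)
            scores, pred = predict(model, ds)
            perm = rng.permutation(ds.n)
            s2, p2 = predict(model, _dataset(ds.X[perm], ds.y[perm]))
            np.testing.assert_allclose(s2, scores[perm], rtol=1e-12)
            np.testing.assert_array_equal(p2, pred[perm])

    def test_scores_bounded(self):
        ds = _blobs()
        for model in (train_lstm(ds, TrainConfig(hidden=4, epochs=3, seed=0)),
                      train_svm(ds, TrainConfig(seed=0))):
            scores, _ = predict(model, ds)
            assert np.all((scores >= 0) & (scores <= 1))
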