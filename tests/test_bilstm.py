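import numpy as np
import pytest

from eegaffect.bilstm import (
    GATES,
    BiLSTMParams,
    DirectionParams,
    FittedBiLSTM,
    TrainConfig,
    bilstm_forward,
    clip_global_norm,
    loss_and_grads,
    lstm_cell_step,
    predict,
    train,
)


def zeroed_direction(input_dim, hidden):
    p = DirectionParams(input_dim, hidden, np.random.default_rng(0))
    for g in GATES:
        setattr(p, f"W{g}", np.zeros((hidden + input_dim, hidden)))
        setattr(p, f"b{g}", np.zeros(hidden))
    return p


def scalar_oracle_step(x, h, c, p):
    """Independent elementwise evaluation of the gate equations."""
    z = np.concatenate([h, x])
    H = h.size
    out_h, out_c = np.empty(H), np.empty(H)
    for j in range(H):
        af = sum(z[k] * p.Wf[k, j] for k in range(z.size)) + p.bf[j]
        ai = sum(z[k] * p.Wi[k, j] for k in range(z.size)) + p.bi[j]
        ac = sum(z[k] * p.Wc[k, j] for k in range(z.size)) + p.bc[j]
        ao = sum(z[k] * p.Wo[k, j] for k in range(z.size)) + p.bo[j]
        f = 1 / (1 + np.exp(-af))
        i = 1 / (1 + np.exp(-ai))
        g = np.tanh(ac)
        o = 1 / (1 + np.exp(-ao))
        out_c[j] = f * c[j] + i * g
        out_h[j] = o * np.tanh(out_c[j])
    return out_h, out_c


class TestCellStep:
    def test_zero_parameters_closed_form(self):
        p = zeroed_direction(2, 3)
        h, c = lstm_cell_step(np.ones(2), np.zeros(3), np.zeros(3), p)
        # all gates sit at sigmoid(0)=0.5, candidate tanh(0)=0
        np.testing.assert_allclose(c, 0.0)
        np.testing.assert_allclose(h, 0.0)

    def test_saturated_forget_gate_preserves_cell(self):
        p = zeroed_direction(2, 3)
        p.bf = np.full(3, 30.0)
        c_prev = np.array([0.3, -1.2, 2.0])
        _, c = lstm_cell_step(np.ones(2), np.zeros(3), c_prev, p)
        np.testing.assert_allclose(c, c_prev, atol=1e-9)

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(8)
        p = DirectionParams(3, 4, rng)
        x, h0, c0 = rng.standard_normal(3), rng.standard_normal(4), rng.standard_normal(4)
        h, c = lstm_cell_step(x, h0, c0, p)
        ho, co = scalar_oracle_step(x, h0, c0, p)
        np.testing.assert_allclose(h, ho, atol=1e-12)
        np.testing.assert_allclose(c, co, atol=1e-12)

    def test_nonfinite_input_names_gate(self):
        p = zeroed_direction(2, 3)
        with pytest.raises(FloatingPointError, match="gate 'f'"):
            lstm_cell_step(np.array([np.inf, 1.0]) , np.ones(3), np.zeros(3), p)


class TestForward:
    def test_scores_sum_to_one(self):
        params = BiLSTMParams(1, 6, 2, seed=0)
        X = np.random.default_rng(0).standard_normal((5, 4, 1))
        s = bilstm_forward(X, params)
        np.testing.assert_allclose(s.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_parameters_give_uniform_scores(self):
        params = BiLSTMParams(1, 4, 1, seed=0)
        for name, val in list(params.param_items()):
            params.set_(name, np.zeros_like(val))
        s = bilstm_forward(np.random.default_rng(1).standard_normal((3, 5, 1)), params)
        np.testing.assert_allclose(s, 0.5, atol=1e-12)

    def test_directional_symmetry_under_reversal(self):
        # reversing time and swapping direction blocks (and the two dense
        # halves) must leave the scores unchanged
        params = BiLSTMParams(1, 5, 2, seed=4)
        swapped = BiLSTMParams(1, 5, 2, seed=4)
        for layer, slayer in zip(params.layers, swapped.layers):
            slayer["fwd"], slayer["bwd"] = layer["bwd"], layer["fwd"]
            if "Wcf" in layer:
                slayer["Wcf"], slayer["Wcb"] = layer["Wcb"], layer["Wcf"]
        H = params.hidden
        swapped.Wdense = np.vstack([params.Wdense[H:], params.Wdense[:H]])
        X = np.random.default_rng(2).standard_normal((4, 6, 1))
        np.testing.assert_allclose(
            bilstm_forward(X, params),
            bilstm_forward(X[:, ::-1], swapped),
            atol=1e-12,
        )

    def test_empty_sequence_rejected(self):
        params = BiLSTMParams(1, 3, 1, seed=0)
        with pytest.raises(ValueError, match="empty"):
            bilstm_forward(np.empty((2, 0, 1)), params)

    def test_gradients_match_finite_differences(self):
        params = BiLSTMParams(1, 4, 2, seed=3, dtype=np.float64)
        rng = np.random.default_rng(5)
        X = rng.standard_normal((3, 3, 1))
        y = np.array([0, 1, 1])
        _, grads = loss_and_grads(X, y, params)
        eps = 1e-6
        for name, val in params.param_items():
            num = np.zeros_like(val)
            it = np.nditer(val, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = val[idx]
                val[idx] = orig + eps
                lp, _ = loss_and_grads(X, y, params)
                val[idx] = orig - eps
                lm, _ = loss_and_grads(X, y, params)
                val[idx] = orig
                num[idx] = (lp - lm) / (2 * eps)
            # relative check with an absolute floor against FD roundoff
            denom = np.maximum(np.abs(grads[name]) + np.abs(num), 1e-4)
            assert np.max(np.abs(grads[name] - num) / denom) < 1e-5, name


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(0)
    y = rng.integers(0, 2, 400)
    X = rng.standard_normal((400, 10))
    X[:, 2] += 3.0 * y
    X[:, 7] -= 2.0 * y
    return X, y


@pytest.fixture(scope="module")
def fitted(separable):
    X, y = separable
    return train(X, y, TrainConfig(hidden_units=32, max_epochs=20, seed=0))


class TestTraining:
    def test_learns_separable_planted_data(self, fitted):
        assert fitted.accuracy_trace[-1] >= 0.95

    def test_initial_loss_near_ln2(self, fitted):
        assert fitted.loss_trace[0] == pytest.approx(np.log(2), abs=0.1)

    def test_gradient_norms_respect_clip(self, fitted):
        assert max(fitted.gradient_norms) <= 1.0 + 1e-6

    def test_zero_learning_rate_freezes_parameters(self, separable):
        X, y = separable
        cfg = TrainConfig(hidden_units=8, max_epochs=3, learning_rate=0.0,
                          seed=1, minibatch_size=400)
        model = train(X[:50], y[:50], cfg)
        ref = BiLSTMParams(1, 8, cfg.n_layers, seed=1, dtype=np.float32)
        for name, val in model.params.param_items():
            np.testing.assert_array_equal(val, ref.get(name))
        assert len(set(np.round(model.loss_trace, 12))) == 1

    def test_training_is_deterministic(self, separable):
        X, y = separable
        cfg = TrainConfig(hidden_units=8, max_epochs=2, seed=5)
        a = train(X[:100], y[:100], cfg)
        b = train(X[:100], y[:100], cfg)
        assert a.loss_trace == b.loss_trace

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            train(np.zeros((10, 3)), np.zeros(10, dtype=int), TrainConfig())

    def test_predict_consistency_and_probabilities(self, fitted, separable):
        X, y = separable
        labels, probs = predict(fitted, X)
        assert np.all((probs >= 0) & (probs <= 1))
        np.testing.assert_array_equal(labels, (probs >= 0.5).astype(int))
        assert (labels == y).mean() == pytest.approx(fitted.accuracy_trace[-1], abs=0.05)

    def test_column_mismatch_names_missing(self, fitted):
        from eegaffect.features import FeatureMatrix

        fm = FeatureMatrix(np.zeros((2, 3)), ["a", "b", "c"])
        with pytest.raises(ValueError, match="missing"):
            predict(fitted, fm)

    def test_save_load_round_trip_bit_identical(self, fitted, separable, tmp_path):
        X, _ = separable
        fitted.save(tmp_path / "model.npz")
        back = FittedBiLSTM.load(tmp_path / "model.npz")
        _, p0 = predict(fitted, X[:20])
        _, p1 = predict(back, X[:20])
        np.testing.assert_array_equal(p0, p1)


class TestClip:
    def test_clip_scales_to_threshold(self):
        grads = {"a": np.array([3.0, 4.0])}
        norm = clip_global_norm(grads, 1.0)
        assert norm == pytest.approx(5.0)
        assert np.linalg.norm(grads["a"]) == pytest.approx(1.0)

    def test_small_gradients_untouched(self):
        grads = {"a": np.array([0.3])}
        clip_global_norm(grads, 1.0)
        assert grads["a"][0] == pytest.approx(0.3)
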