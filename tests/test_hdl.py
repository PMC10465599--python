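"""CNN-LSTM classifier: gate arithmetic, heads, training behaviour."""

import numpy as np
import pytest

from leafdx import data, hdl, nn


def _zero_lstm_weights(d, h):
    z = lambda *s: np.zeros(s)
    return hdl.LSTMWeights(
        W_ix=z(d, h), W_ih=z(h, h), b_i=z(h),
        W_gx=z(d, h), W_gh=z(h, h),
        W_fx=z(d, h), W_fh=z(h, h), b_f=z(h),
        W_ox=z(d, h), W_oh=z(h, h), b_o=z(h),
    )


class TestLSTMStep:
    def test_all_zero_weights_and_state(self):
        w = _zero_lstm_weights(3, 4)
        h_t, c_t = hdl.lstm_step(np.ones(3), np.zeros(4), np.zeros(4), w)
        assert np.array_equal(c_t, np.zeros(4))
        assert np.array_equal(h_t, np.zeros(4))

    def test_zero_weights_nonzero_cell(self):
        # f = 0.5 halves c_prev = 2 -> c_t = 1; h_t = 0.5 * tanh(1)
        w = _zero_lstm_weights(2, 3)
        h_t, c_t = hdl.lstm_step(np.ones(2), np.zeros(3), np.full(3, 2.0), w)
        assert np.allclose(c_t, 1.0)
        assert np.allclose(h_t, 0.5 * np.tanh(1.0))
        assert h_t[0] == pytest.approx(0.380797, abs=1e-6)

    def test_gate_ranges_with_random_weights(self):
        rng = np.random.default_rng(0)
        d, h = 5, 4
        w = hdl.LSTMWeights(*(rng.standard_normal(s) for s in
                              [(d, h), (h, h), (h,), (d, h), (h, h),
                               (d, h), (h, h), (h,), (d, h), (h, h), (h,)]))
        for _ in range(20):
            x, hp, cp = rng.standard_normal(d), rng.standard_normal(h), rng.standard_normal(h)
            i = hdl.sigmoid(x @ w.W_ix + hp @ w.W_ih + w.b_i)
            f = hdl.sigmoid(x @ w.W_fx + hp @ w.W_fh + w.b_f)
            o = hdl.sigmoid(x @ w.W_ox + hp @ w.W_oh + w.b_o)
            g = np.tanh(x @ w.W_gx + hp @ w.W_gh)
            assert ((i > 0) & (i < 1)).all() and ((f > 0) & (f < 1)).all() and ((o > 0) & (o < 1)).all()
            assert (np.abs(g) < 1).all()
            h_t, _ = hdl.lstm_step(x, hp, cp, w)
            # h = o * tanh(c): both factors strictly below 1 in magnitude
            assert (np.abs(h_t) < 1).all()

    def test_dimension_mismatch_rejected(self):
        w = _zero_lstm_weights(3, 4)
        with pytest.raises(ValueError):
            hdl.lstm_step(np.ones(2), np.zeros(4), np.zeros(4), w)


class TestForward:
    def test_zero_heads_give_uniform_probabilities(self):
        spec = hdl.HDLSpec(n_cr=1, n_crp=2, lstm_hidden=4, in_channels=3, base_width=4)
        model = hdl.HDLModel(spec, image_size=(16, 16), seed=0)
        params = model.named_params()
        for key in list(params):
            if key.startswith(("coarse_head", "fine_head")):
                params[key] = np.zeros_like(params[key])
        model.set_named_params(params)
        p_coarse, p_fine = hdl.hdl_forward(model, np.random.default_rng(0).random((2, 3, 16, 16)))
        assert np.allclose(p_coarse, 0.5, atol=1e-12)
        assert np.allclose(p_fine, 1.0 / 6.0, atol=1e-12)

    def test_probabilities_normalized_for_random_models(self):
        rng = np.random.default_rng(1)
        for seed in range(10):
            spec = hdl.HDLSpec(n_cr=1, n_crp=1, lstm_hidden=3, in_channels=3, base_width=3,
                               head_arrangement="sequential" if seed % 2 else "parallel")
            model = hdl.HDLModel(spec, image_size=(16, 16), seed=seed)
            p_coarse, p_fine = hdl.hdl_forward(model, rng.random((4, 3, 16, 16)))
            assert np.allclose(p_coarse.sum(axis=1), 1.0, atol=1e-6)
            assert np.allclose(p_fine.sum(axis=1), 1.0, atol=1e-6)

    def test_empty_sequence_rejected(self):
        spec = hdl.HDLSpec(n_cr=1, n_crp=1, lstm_hidden=3, in_channels=1, base_width=2)
        model = hdl.HDLModel(spec, image_size=(16, 16), seed=0)
        with pytest.raises(ValueError, match="non-empty"):
            model.lstm.forward(np.zeros((1, 0, model.seq_dim)))

    def test_coarse_label_mapping(self):
        assert [hdl.coarse_of_fine(i) for i in range(1, 7)] == [0, 0, 0, 0, 0, 1]
        with pytest.raises(ValueError):
            hdl.coarse_of_fine(0)


@pytest.fixture(scope="module")
def overfit_run():
    """12 images (2/class), small net, enough epochs to memorize."""
    images, labels = [], []
    i = 0
    for name in data.CLASS_NAMES:
        for _ in range(2):
            img = data.render_leaf(name, (32, 32), noise_sigma=0.02, rng=100 + i)
            images.append(img.pixels.transpose(2, 0, 1))
            labels.append(data.label_of(name).id)
            i += 1
    X, y = np.array(images), np.array(labels)
    spec = hdl.HDLSpec(n_cr=1, n_crp=2, lstm_hidden=16, in_channels=3, base_width=6)
    config = hdl.TrainConfig(epochs=60, batch_size=12, learning_rate=0.01, seed=0)
    model = hdl.train_hdl(X, y, spec, config)
    return X, y, spec, config, model


class TestTraining:
    def test_overfits_tiny_set(self, overfit_run):
        X, y, _, _, model = overfit_run
        assert model.history[-1]["accuracy"] == 1.0
        fine, coarse, probs = hdl.predict(X, model)
        assert np.array_equal(fine, y)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_loss_mostly_non_increasing(self, overfit_run):
        *_, model = overfit_run
        losses = [h["loss"] for h in model.history]
        assert all(np.isfinite(losses))
        ups = sum(1 for a, b in zip(losses, losses[1:]) if b > a + 1e-9)
        assert ups <= 0.05 * len(losses)

    def test_coarse_fine_consistency(self, overfit_run):
        X, _, _, _, model = overfit_run
        fine, coarse, _ = hdl.predict(X, model)
        implied = np.array([hdl.coarse_of_fine(int(f)) for f in fine])
        assert (implied == coarse).mean() >= 0.95

    def test_seeded_determinism(self, overfit_run):
        X, y, spec, config, model = overfit_run
        again = hdl.train_hdl(X, y, spec, config)
        assert [h["loss"] for h in again.history] == [h["loss"] for h in model.history]

    def test_single_class_warns(self):
        X = np.random.default_rng(0).random((4, 3, 16, 16))
        spec = hdl.HDLSpec(n_cr=1, n_crp=1, lstm_hidden=3, in_channels=3, base_width=2)
        with pytest.warns(UserWarning, match="single class"):
            hdl.train_hdl(X, np.array([2, 2, 2, 2]), spec, hdl.TrainConfig(epochs=1, seed=0))

    def test_untrained_model_cannot_predict(self):
        spec = hdl.HDLSpec(n_cr=1, n_crp=1, lstm_hidden=3, in_channels=3, base_width=2)
        model = hdl.HDLModel(spec, image_size=(16, 16))
        with pytest.raises(ValueError, match="not been trained"):
            hdl.predict(np.zeros((1, 3, 16, 16)), model)

    def test_spec_bounds(self):
        with pytest.raises(ValueError):
            hdl.HDLSpec(n_cr=7)
        with pytest.raises(ValueError):
            hdl.HDLSpec(head_arrangement="stacked")
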