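import numpy as np
import pytest

import harlearn as hl
from harlearn.errors import SpecError, TrainingError
from harlearn.nn import (ArchitectureSpec, ConvBlock, LSTMCellParams,
                         build_model, conv_time_length, get_preset,
                         lstm_cell_step, train_autoencoder, train_supervised,
                         extract_features)
from harlearn.nn.layers import LSTMLayer


def scalar_lstm_step(p, x, c_prev, m_prev):
    """Element-by-element reference of the gate equations (pure Python)."""
    import math
    H = len(c_prev)

    def affine(W, U, b, j):
        return (sum(x[i] * W[i][j] for i in range(len(x)))
                + sum(c_prev[i] * U[i][j] for i in range(H)) + b[j])

    sig = lambda z: 1.0 / (1.0 + math.exp(-z))
    c_t, m_t = [], []
    for j in range(H):
        y_i = sig(affine(p.W_i, p.U_i, p.b_i, j))
        y_f = sig(affine(p.W_f, p.U_f, p.b_f, j))
        y_o = sig(affine(p.W_o, p.U_o, p.b_o, j))
        g = math.tanh(affine(p.W, p.U, p.b, j))
        m = y_i * g + y_f * m_prev[j]
        m_t.append(m)
        c_t.append(y_o * math.tanh(m))
    return np.array(c_t), np.array(m_t)


class TestConvTimeLength:
    @pytest.mark.parametrize("args,expected", [
        ((64, 11, 1, 2), 27),       # first recurrent layer, multichannel preset
        ((151, 32, 1, 2), 60),      # triaxial preset
    ])
    def test_preset_cell_counts(self, args, expected):
        assert conv_time_length(*args) == expected

    def test_chained_blocks(self):
        # the three-block convolutional trunk: 64 -> 27 -> 6 -> 1
        L = 64
        for f, p in [(11, 2), (10, 3), (6, 1)]:
            L = conv_time_length(L, f, 1, p)
        assert L == 1

    def test_matches_window_enumeration(self):
        for L in range(1, 120):
            for f in range(1, L + 1):
                for p in (1, 2, 3):
                    positions = len(range(0, L - f + 1))
                    assert conv_time_length(L, f, 1, p) == positions // p

    def test_kernel_longer_than_input_rejected(self):
        with pytest.raises(SpecError):
            conv_time_length(8, 11, 1, 2)


class TestLSTMCell:
    def test_zero_weights_zero_memory(self):
        p = LSTMCellParams(*[np.zeros((2, 3)) if i % 3 == 0 else
                             np.zeros((3, 3)) if i % 3 == 1 else np.zeros(3)
                             for i in range(12)])
        c, m = lstm_cell_step(p, np.zeros(2), np.zeros(3), np.zeros(3))
        np.testing.assert_array_equal(c, 0)
        np.testing.assert_array_equal(m, 0)

    def test_zero_weights_nonzero_memory_scalar_form(self):
        # all weights zero: gates = 0.5, cell input tanh(0)=0,
        # so m_t = 0.5 m_prev and c_t = 0.5 tanh(0.5 m_prev)
        p = LSTMCellParams(*[np.zeros((1, 1)), np.zeros((1, 1)), np.zeros(1)] * 4)
        m_prev = np.array([0.8])
        c, m = lstm_cell_step(p, np.zeros(1), np.zeros(1), m_prev)
        assert m[0] == pytest.approx(0.4)
        assert c[0] == pytest.approx(0.5 * np.tanh(0.4))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_scalar_oracle(self, seed):
        rng = np.random.default_rng(seed)
        D, H = int(rng.integers(1, 4)), int(rng.integers(1, 4))
        p = LSTMCellParams.init(D, H, rng)
        x = rng.normal(size=D)
        c_prev, m_prev = rng.normal(size=H), rng.normal(size=H)
        c, m = lstm_cell_step(p, x, c_prev, m_prev)
        c_ref, m_ref = scalar_lstm_step(p, x, c_prev, m_prev)
        np.testing.assert_allclose(c, c_ref, atol=1e-10)
        np.testing.assert_allclose(m, m_ref, atol=1e-10)

    def test_layer_forward_consistent_with_cell_step(self, rng):
        layer = LSTMLayer(3, 4, rng, return_sequences=True)
        x = rng.normal(size=(2, 5, 3))
        out = layer.forward(x, train=True)
        p = layer.cell_params()
        c = np.zeros((2, 4))
        m = np.zeros((2, 4))
        for t in range(5):
            c, m = lstm_cell_step(p, x[:, t], c, m)
            np.testing.assert_allclose(out[:, t], c, atol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        p = LSTMCellParams.init(2, 3, rng)
        with pytest.raises(SpecError):
            lstm_cell_step(p, np.zeros(5), np.zeros(3), np.zeros(3))


def _finite_difference_check(model, X, y, n_checks=3, eps=1e-6, tol=1e-5):
    logits = model.forward(X, train=True)
    model.loss.forward(logits, y)
    for p in model.params():
        p.zero_grad()
    model.backward(model.loss.backward())
    rng = np.random.default_rng(0)
    for p in model.params():
        flat = p.value.reshape(-1)
        for idx in rng.integers(0, flat.size, size=min(n_checks, flat.size)):
            old = flat[idx]
            flat[idx] = old + eps
            lp = model.loss.forward(model.forward(X, train=True), y)
            flat[idx] = old - eps
            lm = model.loss.forward(model.forward(X, train=True), y)
            flat[idx] = old
            num = (lp - lm) / (2 * eps)
            assert p.grad.reshape(-1)[idx] == pytest.approx(num, rel=1e-4,
                                                            abs=tol)


class TestGradients:
    """Backprop of every family against central finite differences."""

    @pytest.mark.parametrize("family", ["mlp", "cnn", "lstm", "hybrid"])
    def test_supervised_families(self, rng, family):
        spec = {
            "mlp": ArchitectureSpec("mlp", dense_sizes=(6, 6, 6)),
            "cnn": ArchitectureSpec("cnn", conv_blocks=(ConvBlock(3, 1, 4),),
                                    dense_size=6),
            "lstm": ArchitectureSpec("lstm", lstm_dim=4, dense_size=6),
            "hybrid": ArchitectureSpec("hybrid", conv_blocks=(ConvBlock(3, 1, 4),),
                                       lstm_dim=4, dense_size=6),
        }[family]
        model = build_model(spec, T=12, S=3, n_classes=3, seed=1)
        X = rng.normal(size=(6, 12, 3))
        y = rng.integers(0, 3, size=6)
        _finite_difference_check(model, X, y)

    def test_autoencoder(self, rng):
        model = build_model(ArchitectureSpec("ae", ae_hidden=5), T=6, S=2,
                            n_classes=2, seed=1)
        X = rng.normal(size=(5, 6, 2))
        target = X.reshape(5, -1)
        recon = model.forward(X, train=True)
        model.loss.forward(recon, target)
        for p in model.params():
            p.zero_grad()
        model.backward(model.loss.backward())
        eps = 1e-6
        p = model.params()[0]
        old = p.value[0, 0]
        p.value[0, 0] = old + eps
        lp = model.loss.forward(model.forward(X, train=True), target)
        p.value[0, 0] = old - eps
        lm = model.loss.forward(model.forward(X, train=True), target)
        p.value[0, 0] = old
        assert p.grad[0, 0] == pytest.approx((lp - lm) / (2 * eps), rel=1e-4)


class TestBuildModel:
    def test_hybrid_presets_recurrent_steps(self):
        m64 = build_model(get_preset("opportunity", "hybrid"), 64, 107, 18)
        assert m64.lstm_steps == 27
        m151 = build_model(get_preset("unimib", "hybrid"), 151, 3, 17)
        assert m151.lstm_steps == 60

    def test_tiny_preset_builds_and_forwards(self, rng):
        for family in ("mlp", "cnn", "lstm", "hybrid", "ae"):
            model = build_model(get_preset("tiny", family), 32, 4, 3, seed=0)
            out = model.forward(rng.normal(size=(2, 32, 4)), train=True)
            assert out.shape[0] == 2

    def test_feature_dims_match_presets(self):
        assert build_model(get_preset("opportunity", "mlp"), 64, 10, 5
                           ).feature_dim == 2000
        assert build_model(get_preset("opportunity", "ae"), 64, 10, 5
                           ).feature_dim == 5000

    def test_undersized_input_names_offending_block(self):
        spec = get_preset("unimib", "cnn")      # kernel 32 over time
        with pytest.raises(SpecError, match="conv block 1"):
            build_model(spec, T=16, S=3, n_classes=4)


@pytest.fixture(scope="module")
def easy_data():
    rng = np.random.default_rng(0)
    t = np.arange(16) / 30.0
    X = np.empty((80, 16, 2))
    y = np.repeat([0, 1], 40)
    for i in range(80):
        f = 2.0 if y[i] == 0 else 6.0
        X[i] = np.sin(2 * np.pi * f * t)[:, None] + rng.normal(0, .05, (16, 2))
    return X, y


class TestTraining:
    def test_mlp_fits_separable_classes(self, easy_data):
        X, y = easy_data
        model = build_model(get_preset("tiny", "mlp"), 16, 2, 2, seed=0)
        ext = train_supervised(model, X, y, epochs=10, batch_size=16, seed=0)
        preds = model.forward(X, train=False).argmax(axis=1)
        assert (preds == y).mean() >= 0.95
        assert min(ext.history) < ext.history[0]

    def test_zero_epochs_leaves_weights(self, easy_data):
        X, y = easy_data
        model = build_model(get_preset("tiny", "mlp"), 16, 2, 2, seed=0)
        before = [p.value.copy() for p in model.params()]
        train_supervised(model, X, y, epochs=0, seed=0)
        for b, p in zip(before, model.params()):
            np.testing.assert_array_equal(b, p.value)

    def test_same_seed_identical_loss(self, easy_data):
        X, y = easy_data
        runs = []
        for _ in range(2):
            model = build_model(get_preset("tiny", "cnn"), 16, 2, 2, seed=4)
            ext = train_supervised(model, X, y, epochs=3, batch_size=16, seed=4)
            runs.append(ext.history[-1])
        assert runs[0] == runs[1]

    def test_single_class_rejected(self, easy_data):
        X, _ = easy_data
        model = build_model(get_preset("tiny", "mlp"), 16, 2, 2, seed=0)
        with pytest.raises(TrainingError):
            train_supervised(model, X, np.zeros(len(X), dtype=int), epochs=1)

    def test_autoencoder_reconstructs_below_input_variance(self, easy_data):
        X, _ = easy_data
        model = build_model(get_preset("tiny", "ae"), 16, 2, 2, seed=0)
        ext = train_autoencoder(model, X, epochs=30, batch_size=16, seed=0)
        recon = model.forward(X, train=False)
        mse = np.mean((recon - X.reshape(len(X), -1)) ** 2)
        assert mse < X.var()
        assert model.forward(X[:3], train=False).shape == (3, 32)

    def test_extract_features_order_invariant(self, easy_data):
        X, y = easy_data
        model = build_model(get_preset("tiny", "mlp"), 16, 2, 2, seed=0)
        ext = train_supervised(model, X, y, epochs=2, batch_size=16, seed=0)
        F = extract_features(ext, X)
        F_rev = extract_features(ext, X[::-1])
        np.testing.assert_allclose(F, F_rev[::-1], atol=1e-12)
        np.testing.assert_allclose(F[0], F[0])  # deterministic repeat
        assert F.shape == (80, model.feature_dim)

    def test_identical_frames_identical_features(self, easy_data):
        X, y = easy_data
        model = build_model(get_preset("tiny", "cnn"), 16, 2, 2, seed=0)
        ext = train_supervised(model, X, y, epochs=1, batch_size=16, seed=0)
        dup = np.stack([X[0], X[0]])
        F = extract_features(ext, dup)
        np.testing.assert_array_equal(F[0], F[1])
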