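"""ConvLSTM core: convolution, cell, layer, readout, counting, initialization.

Loop-based reference implementations are written from the mathematical
definitions and kept independent of the package's vectorized engine.
"""

import numpy as np
import pytest

import connprint as cp
from connprint.convrnn import CellState
from connprint.errors import ShapeError, ValidationError


# --- independent references ------------------------------------------------


def conv_oracle(x, kernel):
    """Explicit nested-loop "same" cross-correlation, high-side extra pad."""
    k, cin, cout = kernel.shape
    n = x.shape[0]
    lo = (k - 1) // 2
    out = np.zeros((n, cout))
    for j in range(n):
        for u in range(k):
            src = j + u - lo
            if 0 <= src < n:
                for a in range(cin):
                    for b in range(cout):
                        out[j, b] += x[src, a] * kernel[u, a, b]
    return out


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def step_oracle(x_t, h, c, w):
    """Gate-by-gate ConvLSTM step using the loop convolution."""
    f = w.recurrent_kernel.shape[1]
    z = conv_oracle(x_t, w.input_kernel) + conv_oracle(h, w.recurrent_kernel) + w.bias
    i = sigmoid(z[:, :f])
    fg = sigmoid(z[:, f : 2 * f])
    g = np.tanh(z[:, 2 * f : 3 * f])
    o = sigmoid(z[:, 3 * f :])
    c_new = fg * c + i * g
    h_new = o * np.tanh(c_new)
    return h_new, c_new


def layer_oracle(clip, w, mode):
    """Unrolled step oracle plus batch normalization and ReLU."""
    n_time, n_space, _ = clip.shape
    f = w.recurrent_kernel.shape[1]
    h = np.zeros((n_space, f))
    c = np.zeros((n_space, f))
    hs = []
    for t in range(n_time):
        h, c = step_oracle(clip[t], h, c, w)
        hs.append(h)
    hseq = np.stack(hs)
    if mode == "train":
        mean = hseq.mean(axis=(0, 1))
        var = hseq.var(axis=(0, 1))
    else:
        mean, var = w.bn_moving_mean, w.bn_moving_var
    xhat = (hseq - mean) / np.sqrt(var + 1e-5)
    return np.maximum(w.bn_gamma * xhat + w.bn_beta, 0.0)


def random_layer_weights(rng, k, cin, f):
    return cp.ConvLstmLayerWeights(
        input_kernel=rng.standard_normal((k, cin, 4 * f)),
        recurrent_kernel=0.5 * rng.standard_normal((k, f, 4 * f)),
        bias=0.1 * rng.standard_normal(4 * f),
        bn_gamma=1.0 + 0.1 * rng.standard_normal(f),
        bn_beta=0.1 * rng.standard_normal(f),
        bn_moving_mean=0.1 * rng.standard_normal(f),
        bn_moving_var=np.abs(1.0 + 0.1 * rng.standard_normal(f)),
    )


# --- conv1d_same -----------------------------------------------------------


class TestConv1dSame:
    def test_identity_tap_returns_input(self):
        x = np.arange(4.0).reshape(4, 1)
        kernel = np.array([1.0, 0.0]).reshape(2, 1, 1)
        np.testing.assert_array_equal(cp.conv1d_same(x, kernel), x)

    def test_three_point_sum_with_trailing_pad(self):
        x = np.array([[1.0], [2.0], [3.0]])
        kernel = np.array([1.0, 1.0]).reshape(2, 1, 1)
        np.testing.assert_array_equal(
            cp.conv1d_same(x, kernel).ravel(), [3.0, 5.0, 3.0]
        )

    @pytest.mark.parametrize("k,cin,cout", [(1, 1, 2), (2, 3, 2), (3, 2, 4), (5, 1, 1)])
    def test_matches_nested_loop_reference(self, rng, k, cin, cout):
        for _ in range(10):
            x = rng.standard_normal((rng.integers(k, 12), cin))
            kernel = rng.standard_normal((k, cin, cout))
            np.testing.assert_allclose(
                cp.conv1d_same(x, kernel), conv_oracle(x, kernel), atol=1e-10
            )

    def test_channel_mismatch_is_shape_error(self, rng):
        with pytest.raises(ShapeError):
            cp.conv1d_same(rng.standard_normal((5, 3)), rng.standard_normal((2, 2, 4)))


# --- ConvLSTM cell ----------------------------------------------------------


class TestConvLstmStep:
    def test_zero_weights_zero_state_stay_zero(self):
        f, k, cin, n = 2, 2, 1, 5
        w = cp.ConvLstmLayerWeights(
            input_kernel=np.zeros((k, cin, 4 * f)),
            recurrent_kernel=np.zeros((k, f, 4 * f)),
            bias=np.zeros(4 * f),
            bn_gamma=np.ones(f),
            bn_beta=np.zeros(f),
            bn_moving_mean=np.zeros(f),
            bn_moving_var=np.ones(f),
        )
        state = cp.convlstm_step(np.ones((n, cin)), CellState.zeros(n, f), w)
        assert np.all(state.h == 0.0)
        assert np.all(state.c == 0.0)

    def test_matches_gatewise_reference(self, rng):
        for _ in range(25):
            k = int(rng.integers(1, 4))
            cin = int(rng.integers(1, 4))
            f = int(rng.integers(1, 4))
            n = int(rng.integers(k, 8))
            w = random_layer_weights(rng, k, cin, f)
            x = rng.standard_normal((n, cin))
            h0 = rng.standard_normal((n, f))
            c0 = rng.standard_normal((n, f))
            state = cp.convlstm_step(x, CellState(h=h0.copy(), c=c0.copy()), w)
            h_ref, c_ref = step_oracle(x, h0, c0, w)
            np.testing.assert_allclose(state.h, h_ref, atol=1e-8)
            np.testing.assert_allclose(state.c, c_ref, atol=1e-8)

    def test_gate_ranges(self, rng):
        # i, f, o in (0, 1) and |g| < 1 imply |c| grows at most additively
        w = random_layer_weights(rng, 2, 1, 3)
        state = CellState.zeros(6, 3)
        for t in range(20):
            state = cp.convlstm_step(rng.standard_normal((6, 1)), state, w)
        assert np.all(np.abs(state.c) < 21.0)
        assert np.all(np.abs(state.h) < 1.0)


class TestLayerForward:
    def test_zero_weights_give_zero_output(self):
        f = 2
        w = cp.ConvLstmLayerWeights(
            input_kernel=np.zeros((2, 1, 4 * f)),
            recurrent_kernel=np.zeros((2, f, 4 * f)),
            bias=np.zeros(4 * f),
            bn_gamma=np.ones(f),
            bn_beta=np.zeros(f),
            bn_moving_mean=np.zeros(f),
            bn_moving_var=np.ones(f),
        )
        out = cp.layer_forward(np.ones((4, 6, 1)), w, mode="inference")
        assert np.all(out == 0.0)

    @pytest.mark.parametrize("mode", ["train", "inference"])
    def test_matches_unrolled_reference(self, rng, mode):
        for _ in range(10):
            f = int(rng.integers(1, 4))
            cin = int(rng.integers(1, 3))
            w = random_layer_weights(rng, 2, cin, f)
            clip = rng.standard_normal((5, 7, cin))
            got = cp.layer_forward(clip, w, mode=mode)
            np.testing.assert_allclose(got, layer_oracle(clip, w, mode), atol=1e-8)

    def test_output_nonnegative_and_shape_preserving(self, rng):
        w = random_layer_weights(rng, 2, 1, 3)
        out = cp.layer_forward(rng.standard_normal((8, 11, 1)), w)
        assert out.shape == (8, 11, 3)
        assert np.all(out >= 0.0)


# --- full model -------------------------------------------------------------


class TestForward:
    def test_probabilities_normalized(self, rng):
        cfg = cp.ModelConfig(n_rois=9, n_classes=5, layer_filters=(2, 3))
        model = cp.ConvRnnModel(cfg, cp.initialize_weights(cfg, seed=0))
        probs, feat = cp.forward(model, rng.standard_normal((6, 9)))
        assert probs.shape == (5,)
        assert np.all(probs >= 0)
        assert abs(probs.sum() - 1.0) < 1e-6
        assert feat.shape == (9 * 3,)

    def test_single_step_clip_equals_its_own_average(self, rng):
        cfg = cp.ModelConfig(n_rois=6, n_classes=3, layer_filters=(2,))
        model = cp.ConvRnnModel(cfg, cp.initialize_weights(cfg, seed=1))
        clip = rng.standard_normal((1, 6))
        _, feat = cp.forward(model, clip)
        layer_out = cp.layer_forward(clip[:, :, None], model.weights.layers[0])
        np.testing.assert_allclose(feat, layer_out[0].reshape(-1), atol=1e-10)

    def test_wrong_roi_count_is_shape_error(self, rng):
        cfg = cp.ModelConfig(n_rois=6, n_classes=3, layer_filters=(2,))
        model = cp.ConvRnnModel(cfg, cp.initialize_weights(cfg, seed=1))
        with pytest.raises(ShapeError):
            cp.forward(model, rng.standard_normal((4, 7)))

    def test_batched_inference_agrees_with_single_clip_path(self, rng):
        cfg = cp.ModelConfig(n_rois=8, n_classes=4, layer_filters=(3, 2))
        model = cp.ConvRnnModel(cfg, cp.initialize_weights(cfg, seed=2))
        clips = rng.standard_normal((5, 7, 8))
        batched = cp.predict_proba(model, clips)
        for i in range(5):
            single, _ = cp.forward(model, clips[i])
            np.testing.assert_allclose(batched[i], single, atol=1e-4)


class TestCountParameters:
    def test_toy_config_hand_count(self):
        cfg = cp.ModelConfig(n_rois=4, n_classes=3, layer_filters=(2,))
        total, feature = cp.count_parameters(cfg)
        # input 2*1*8=16, recurrent 2*2*8=32, bias 8, bn 4*2=8 -> 64
        assert feature == 64
        assert total == 64 + (4 * 2) * 3 + 3

    def test_matches_instantiated_container_sizes(self):
        cfg = cp.ModelConfig(n_rois=10, n_classes=7, layer_filters=(3, 5), kernel_size=2)
        weights = cp.initialize_weights(cfg, seed=0)
        total, feature = cp.count_parameters(cfg)
        actual = sum(arr.size for _, arr in weights.all_arrays())
        actual_feature = actual - weights.classifier_weight.size - weights.classifier_bias.size
        assert total == actual
        assert feature == actual_feature

    def test_zero_layers_have_no_feature_parameters(self):
        cfg = cp.ModelConfig(n_rois=4, n_classes=3, layer_filters=())
        total, feature = cp.count_parameters(cfg)
        assert feature == 0
        assert total == 3  # classifier bias only (empty feature vector)


class TestInitializeWeights:
    def test_deterministic(self):
        cfg = cp.ModelConfig(n_rois=6, n_classes=4, layer_filters=(2, 3))
        a = cp.initialize_weights(cfg, seed=42)
        b = cp.initialize_weights(cfg, seed=42)
        for (_, x), (_, y) in zip(a.all_arrays(), b.all_arrays()):
            np.testing.assert_array_equal(x, y)

    def test_recurrent_kernels_orthogonal(self):
        cfg = cp.ModelConfig(n_rois=6, n_classes=4, layer_filters=(4, 8))
        w = cp.initialize_weights(cfg, seed=0)
        for lw in w.layers:
            k, f, four_f = lw.recurrent_kernel.shape
            m = lw.recurrent_kernel.reshape(k * f, four_f)
            gram = m @ m.T if k * f <= four_f else m.T @ m
            np.testing.assert_allclose(gram, np.eye(min(k * f, four_f)), atol=1e-6)

    def test_xavier_bound_respected(self):
        cfg = cp.ModelConfig(n_rois=236, n_classes=100)
        w = cp.initialize_weights(cfg, seed=0)
        k = cfg.kernel_size
        for li, lw in enumerate(w.layers):
            cin = cfg.in_channels(li)
            bound = np.sqrt(6.0 / (k * cin + k * 4 * cfg.layer_filters[li]))
            assert np.abs(lw.input_kernel).max() <= bound

    def test_bias_and_bn_at_identity(self):
        w = cp.initialize_weights(cp.ModelConfig(n_rois=5, n_classes=2, layer_filters=(2,)))
        lw = w.layers[0]
        assert np.all(lw.bias == 0)
        assert np.all(lw.bn_gamma == 1) and np.all(lw.bn_beta == 0)
        assert np.all(lw.bn_moving_mean == 0) and np.all(lw.bn_moving_var == 1)


class TestCheckpoint:
    def test_roundtrip_preserves_weights_config_and_labels(self, tmp_path, rng):
        cfg = cp.ModelConfig(n_rois=6, n_classes=3, layer_filters=(2, 4), recurrent_l2=0.01)
        model = cp.ConvRnnModel(
            cfg, cp.initialize_weights(cfg, seed=8), label_map={"a": 0, "b": 1, "c": 2}
        )
        path = tmp_path / "model.h5"
        cp.save_checkpoint(model, path)
        back = cp.load_checkpoint(path)
        assert back.config == cfg
        assert back.label_map == model.label_map
        for (_, x), (_, y) in zip(model.weights.all_arrays(), back.weights.all_arrays()):
            np.testing.assert_array_equal(x, y)
        clip = rng.standard_normal((5, 6))
        np.testing.assert_allclose(
            cp.forward(model, clip)[0], cp.forward(back, clip)[0], atol=1e-12
        )

    def test_bad_mode_rejected(self, rng):
        cfg = cp.ModelConfig(n_rois=4, n_classes=2, layer_filters=(2,))
        model = cp.ConvRnnModel(cfg, cp.initialize_weights(cfg, seed=0))
        with pytest.raises(ValidationError):
            cp.forward(model, rng.standard_normal((3, 4)), mode="predict")
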