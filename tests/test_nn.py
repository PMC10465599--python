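"""Network primitives vs brute-force oracles; SqueezeNet topology checks."""

import numpy as np
import pytest

from leafdx import nn, squeezenet
from leafdx.squeezenet import FireModuleSpec
from conftest import brute_conv_layer


class TestConvLayer:
    def test_identity_1x1_kernel(self):
        x = np.random.default_rng(0).random((2, 1, 4, 4))
        out = nn.conv2d(x, np.ones((1, 1, 1, 1)), np.zeros(1))
        assert np.allclose(out, x)

    def test_zero_input_gives_bias(self):
        out = nn.conv2d(np.zeros((1, 2, 5, 5)), np.random.default_rng(1).random((3, 2, 3, 3)), np.array([1.0, -2.0, 0.5]))
        for p, b in enumerate((1.0, -2.0, 0.5)):
            assert np.allclose(out[0, p], b)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((1, 1, 4, 4)) if seed % 2 else rng.standard_normal((2, 3, 5, 5))
        kernels = rng.standard_normal((2, x.shape[1], 3, 3))
        biases = rng.standard_normal(2)
        pad = seed % 2
        got = nn.conv2d(x, kernels, biases, padding=pad)
        want = brute_conv_layer(x, kernels, biases, padding=pad)
        assert np.allclose(got, want, atol=1e-10)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="channel mismatch"):
            nn.conv2d(np.zeros((1, 2, 4, 4)), np.zeros((1, 3, 3, 3)), np.zeros(1))
        with pytest.raises(ValueError, match="stride"):
            nn.conv2d(np.zeros((1, 1, 4, 4)), np.zeros((1, 1, 3, 3)), np.zeros(1), stride=2)


class TestReLU:
    def test_elementwise_definition(self):
        assert np.array_equal(nn.relu(np.array([-1.0, 0.0, 2.0])), [0.0, 0.0, 2.0])
        assert np.array_equal(nn.relu(np.full(5, -3.0)), np.zeros(5))

    def test_idempotent_on_random_arrays(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            x = rng.standard_normal(rng.integers(1, 20))
            assert np.array_equal(nn.relu(nn.relu(x)), nn.relu(x))


class TestAvgPool:
    def test_single_block(self):
        out = nn.avg_pool_2x2(np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert out.shape == (1, 1) and out[0, 0] == 2.5

    def test_constant_preserved_at_half_resolution(self):
        out = nn.avg_pool_2x2(np.full((1, 2, 6, 8), 0.3))
        assert out.shape == (1, 2, 3, 4)
        assert np.allclose(out, 0.3)

    @pytest.mark.parametrize("seed", range(5))
    def test_sum_conservation(self, seed):
        x = np.random.default_rng(seed).random((6, 6))
        out = nn.avg_pool_2x2(x)
        assert 4.0 * out.sum() == pytest.approx(x.sum(), abs=1e-10)

    def test_odd_dimension_warns_and_truncates(self):
        with pytest.warns(UserWarning, match="odd"):
            out = nn.avg_pool_2x2(np.ones((5, 5)))
        assert out.shape == (2, 2)


class TestFireModule:
    def test_output_channels_and_spatial_size(self):
        spec = FireModuleSpec(s1x1=2, e1x1=3, e3x3=5)
        fire = squeezenet.Fire(4, spec, np.random.default_rng(0))
        out = fire.forward(np.random.default_rng(1).random((2, 4, 8, 8)))
        assert out.shape == (2, 8, 8, 8)
        assert spec.out_channels == 8

    def test_zero_weights_give_zero_output(self):
        spec = FireModuleSpec(s1x1=2, e1x1=2, e3x3=2)
        fire = squeezenet.Fire(3, spec, np.random.default_rng(0))
        params = fire.named_params()
        fire.set_named_params({k: np.zeros_like(v) for k, v in params.items()})
        out = fire.forward(np.random.default_rng(2).random((1, 3, 6, 6)))
        assert np.array_equal(out, np.zeros_like(out))

    def test_composition_of_primitives(self):
        # fire == relu(conv1x1) -> [relu(conv1x1) || relu(conv3x3 pad 1)] concat
        rng = np.random.default_rng(3)
        spec = FireModuleSpec(s1x1=3, e1x1=2, e3x3=4)
        fire = squeezenet.Fire(4, spec, np.random.default_rng(0))
        x = rng.standard_normal((2, 4, 8, 8))
        p = fire.named_params()
        s = nn.relu(nn.conv2d(x, p["squeeze.W"], p["squeeze.b"]))
        e1 = nn.relu(nn.conv2d(s, p["expand1.W"], p["expand1.b"]))
        e3 = nn.relu(nn.conv2d(s, p["expand3.W"], p["expand3.b"], padding=1))
        want = np.concatenate([e1, e3], axis=1)
        assert np.allclose(fire.forward(x), want, atol=1e-12)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            FireModuleSpec(s1x1=0, e1x1=2, e3x3=2)
        with pytest.raises(ValueError):
            FireModuleSpec(s1x1=9, e1x1=2, e3x3=2)


class TestModifiedSqueezeNet:
    def test_declared_topology_counts(self):
        net = squeezenet.build_modified_squeezenet()
        assert net.spec.fire_count == 4
        assert net.spec.layer_count == 39
        assert net.spec.connection_count == 42
        assert all(s == 1 for s in net.spec.conv_strides)
        assert net.spec.dropout_count >= 1

    def test_forward_pass_shape_and_finiteness(self):
        net = squeezenet.build_modified_squeezenet(feature_dim=12, seed=1)
        image = np.random.default_rng(0).random((3, 64, 64))
        feats = squeezenet.extract_features(image, net)
        assert feats.shape == (1, 12)
        assert np.isfinite(feats).all()

    def test_eval_mode_is_deterministic(self):
        net = squeezenet.build_modified_squeezenet(feature_dim=8, dropout_rate=0.5, seed=2)
        x = np.random.default_rng(1).random((2, 3, 32, 32))
        a = squeezenet.extract_features(x, net)
        b = squeezenet.extract_features(x, net)
        assert np.array_equal(a, b)

    def test_zero_network_maps_zero_image_to_zero_vector(self):
        net = squeezenet.build_modified_squeezenet(feature_dim=4, seed=0)
        params = net.named_params()
        net.set_named_params({k: np.zeros_like(v) for k, v in params.items()})
        feats = squeezenet.extract_features(np.zeros((1, 3, 32, 32)), net)
        assert np.array_equal(feats, np.zeros((1, 4)))

    def test_background_invariance_under_roi_masking(self):
        # two images differing only outside the ROI give identical features
        # once the mask zeroes the background upstream
        from leafdx import data, segmentation

        rng = np.random.default_rng(4)
        img = data.render_leaf("iron_deficient", (32, 32), noise_sigma=0.02, rng=1).pixels
        mask = data.leaf_mask((32, 32))
        other = img.copy()
        other[~mask] = rng.random(((~mask).sum(), 3))  # scramble background
        net = squeezenet.build_modified_squeezenet(feature_dim=6, seed=3)
        a = squeezenet.extract_features(segmentation.apply_roi(img, mask).transpose(2, 0, 1), net)
        b = squeezenet.extract_features(segmentation.apply_roi(other, mask).transpose(2, 0, 1), net)
        assert np.allclose(a, b, atol=1e-12)

    def test_checkpoint_roundtrip(self, tmp_path):
        net = squeezenet.build_modified_squeezenet(feature_dim=5, seed=6)
        squeezenet.save_weights(tmp_path / "w.npz", net)
        net2 = squeezenet.build_modified_squeezenet(feature_dim=5, seed=99)
        squeezenet.load_weights(tmp_path / "w.npz", net2)
        x = np.random.default_rng(0).random((1, 3, 32, 32))
        assert np.array_equal(net.forward(x), net2.forward(x))
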