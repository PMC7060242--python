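"""Architecture contracts: pyramid, tiling, feature shapes, heads, losses."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathscore.exceptions import ConfigurationError
from pathscore.model import (ModelSpec, MultiScaleNet, binary_cross_entropy,
                             categorical_cross_entropy, count_parameters,
                             downsample, embed, global_average_pool,
                             load_checkpoint, patchify, save_checkpoint,
                             unpatchify)


@pytest.fixture(scope="module")
def default_spec():
    return ModelSpec()


@pytest.fixture(scope="module")
def tiny_net():
    spec = ModelSpec(scales=(64, 32), patch=32, filters=(4, 8), fc_widths=(10,),
                     dropout=0.0)
    return MultiScaleNet(spec, seed=0)


class TestModelSpec:
    def test_default_geometry(self, default_spec):
        assert default_spec.scales == (1024, 512, 256)
        assert default_spec.patches_per_scale() == (16, 4, 1)
        assert default_spec.n_patches == 21
        assert default_spec.feature_side == 8
        assert default_spec.feature_channels == 64
        assert default_spec.embedding_dim == 21 * 64 == 1344

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"scales": (512, 1024)},           # not decreasing
            {"scales": (1000, 500), "patch": 256},  # patch does not divide
            {"patch": 48},                      # not divisible by 2^5
            {"dropout": 1.0},
            {"head": "banana"},
            {"kernel": 4},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            ModelSpec(**kwargs)

    @settings(deadline=None, max_examples=30)
    @given(
        n_scales=st.integers(1, 3),
        patch_exp=st.integers(5, 7),
        channels=st.integers(8, 64),
    )
    def test_patch_count_and_embedding_formulas(self, n_scales, patch_exp, channels):
        patch = 2**patch_exp
        scales = tuple(patch * 2**i for i in reversed(range(n_scales)))
        spec = ModelSpec(scales=scales, patch=patch,
                         filters=(4, 8, 16, 32, channels))
        expected_patches = sum(4**i for i in range(n_scales))
        assert spec.n_patches == expected_patches
        assert spec.embedding_dim == expected_patches * channels


class TestPyramidAndTiling:
    def test_pyramid_sides_match_scales(self, rng):
        img = rng.random((1024, 1024, 3)).astype(np.float32)
        pyr = downsample(img, (1024, 512, 256))
        assert [p.shape[0] for p in pyr] == [1024, 512, 256]
        # largest scale untouched
        assert pyr[0] is img

    def test_downsampling_preserves_constants(self):
        img = np.full((512, 512, 3), 0.37, np.float32)
        for p in downsample(img, (512, 256, 128)):
            np.testing.assert_allclose(p, 0.37, rtol=1e-6)

    def test_patch_counts_over_pyramid(self, rng):
        img = rng.random((1024, 1024, 3)).astype(np.float32)
        counts = [len(patchify(p, 256)) for p in downsample(img, (1024, 512, 256))]
        assert counts == [16, 4, 1]
        assert sum(counts) == 21

    def test_patchify_roundtrip_and_order_sensitivity(self, rng):
        img = rng.random((256, 256, 3)).astype(np.float32)
        patches = patchify(img, 64)
        np.testing.assert_array_equal(unpatchify(patches, 256), img)
        shuffled = patches[::-1]
        assert not np.array_equal(
            embed([p.mean(axis=(0, 1)) for p in patches]),
            embed([p.mean(axis=(0, 1)) for p in shuffled]),
        )

    def test_global_average_pool(self):
        block = np.array([[[1.0], [2.0]], [[3.0], [4.0]]])  # 2x2x1
        assert global_average_pool(block)[0] == pytest.approx(2.5)
        big = np.random.default_rng(0).random((8, 8, 64))
        assert global_average_pool(big).shape == (64,)


class TestFeatureExtraction:
    def test_feature_block_shape_default(self, default_spec):
        net = MultiScaleNet(default_spec, seed=0)
        patch = np.random.default_rng(1).random((256, 256, 3)).astype(np.float32)
        block = net.extract_features(patch, scale_index=0)
        assert block.shape == (8, 8, 64)

    def test_per_module_channel_schedule(self, default_spec):
        net = MultiScaleNet(default_spec, seed=0)
        x = np.random.default_rng(2).random((1, 256, 256, 3)).astype(np.float32)
        ex = net.extractors[0][0]
        side = 256
        for mi, c_out in enumerate(default_spec.filters):
            for layer in ex.layers[mi * 4 : (mi + 1) * 4]:
                x = layer.forward(x)
            side //= 2
            assert x.shape == (1, side, side, c_out)

    def test_zero_patch_zero_biases_gives_zero_block(self, tiny_net):
        # biases start at zero; gamma*xh+beta of an all-zero input is zero
        patch = np.zeros((32, 32, 3), np.float32)
        block = tiny_net.extract_features(patch, scale_index=1)
        np.testing.assert_allclose(block, 0.0, atol=1e-7)


class TestForward:
    def test_activation_head_strictly_inside_unit_interval(self, tiny_net, rng):
        x = rng.random((3, 64, 64, 3)).astype(np.float32)
        s = tiny_net.predict(x)
        assert s.shape == (3,)
        assert ((s > 0) & (s < 1)).all()

    def test_gene_head_softmax_sums_to_one(self, rng):
        spec = ModelSpec(scales=(64,), patch=64, filters=(2, 4), fc_widths=(8,),
                         head="gene", n_genes=7, dropout=0.0)
        net = MultiScaleNet(spec, seed=3)
        p = net.predict(rng.random((5, 64, 64, 3)).astype(np.float32))
        assert p.shape == (5, 7)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_equal_logits_give_uniform_gene_probabilities(self):
        from pathscore.nn import softmax

        p = softmax(np.zeros((1, 7)))
        np.testing.assert_allclose(p, 1 / 7, atol=1e-12)

    def test_inference_is_deterministic(self, tiny_net, rng):
        x = rng.random((2, 64, 64, 3)).astype(np.float32)
        np.testing.assert_array_equal(tiny_net.predict(x), tiny_net.predict(x))

    def test_wrong_input_side_rejected(self, tiny_net, rng):
        with pytest.raises(ConfigurationError):
            tiny_net.forward(rng.random((1, 32, 32, 3)).astype(np.float32))


class TestParameterCount:
    def test_matches_closed_form_layer_sum(self, default_spec):
        spec = default_spec

        def extractor_params():
            total, c_in = 0, 3
            for c_out in spec.filters:
                total += spec.kernel**2 * c_in * c_out + c_out  # conv w + b
                total += 2 * c_out                              # BN gamma + beta
                c_in = c_out
            return total

        def head_params():
            total, d = 0, spec.embedding_dim
            for w in spec.fc_widths:
                total += d * w + w
                d = w
            return total + d * 1 + 1  # sigmoid output unit

        expected = 3 * extractor_params() + head_params()  # one extractor per scale
        assert count_parameters(spec) == expected

    def test_well_under_a_million(self, default_spec):
        assert count_parameters(default_spec) < 1_000_000

    def test_wider_fc_strictly_increases_count(self, default_spec):
        wider = ModelSpec(fc_widths=(200, 200, 200))
        assert count_parameters(wider) > count_parameters(default_spec)

    def test_sharing_across_scales_reduces_count(self):
        shared = ModelSpec(share_across_scales=True)
        assert count_parameters(shared) < count_parameters(ModelSpec())


class TestLosses:
    def test_perfect_prediction_near_zero_loss(self):
        onehot = np.eye(7)[[0, 3]]
        assert categorical_cross_entropy(onehot, onehot) < 1e-9
        assert binary_cross_entropy([1.0, 0.0], [1, 0]) < 1e-9

    def test_uniform_sevenway_is_log7(self):
        probs = np.full((4, 7), 1 / 7)
        onehot = np.eye(7)[[0, 1, 2, 3]]
        assert categorical_cross_entropy(probs, onehot) == pytest.approx(np.log(7))

    def test_coin_flip_binary_is_log2(self):
        assert binary_cross_entropy([0.5], [1]) == pytest.approx(np.log(2))

    def test_logit_losses_agree_with_probability_losses(self, rng):
        from pathscore.nn import bce_with_logits, ce_with_logits, sigmoid, softmax

        z = rng.normal(0, 2, 10)
        y = rng.integers(0, 2, 10).astype(float)
        l1, _ = bce_with_logits(z, y)
        assert l1 == pytest.approx(binary_cross_entropy(sigmoid(z), y))
        zg = rng.normal(0, 2, (6, 7))
        onehot = np.eye(7)[rng.integers(0, 7, 6)]
        l2, _ = ce_with_logits(zg, onehot)
        assert l2 == pytest.approx(categorical_cross_entropy(softmax(zg), onehot))


class TestCheckpoint:
    def test_roundtrip_preserves_predictions(self, tiny_net, rng, tmp_path):
        x = rng.random((2, 64, 64, 3)).astype(np.float32)
        before = tiny_net.predict(x)
        path = tmp_path / "model.npz"
        save_checkpoint(path, tiny_net)
        restored = load_checkpoint(path)
        np.testing.assert_array_equal(restored.predict(x), before)

    def test_state_mismatch_detected(self, tiny_net):
        other = MultiScaleNet(ModelSpec(scales=(64,), patch=64, filters=(2, 4),
                                        fc_widths=(8,)), seed=0)
        with pytest.raises(ConfigurationError):
            tiny_net.load_state(other.copy_state())
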