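"""Forward-graph contracts: shapes, attention ranges, ablation hooks,
determinism, gradient connectivity, checkpointing."""

import numpy as np
import pytest

from lapseg.network import (
    AttentionOutputs,
    HeadOutputs,
    MultiScaleAttentionNet,
    NetworkConfig,
    decode_boxes,
    final_segmentation,
)
from lapseg.nn import Tensor


def random_image(rng, h=32, w=32):
    return rng.random((h, w, 3)).astype(np.float32)


class TestConfig:
    def test_even_spatial_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            NetworkConfig(spatial_kernel=4)

    def test_reduction_ratio_must_divide(self):
        with pytest.raises(ValueError, match="divide"):
            NetworkConfig(fused_channels=30, channel_reduction_ratio=16)

    def test_unknown_modes_rejected(self):
        with pytest.raises(ValueError, match="upsample_mode"):
            NetworkConfig(upsample_mode="nearest")
        with pytest.raises(ValueError, match="downsample_mode"):
            NetworkConfig(downsample_mode="avg")


class TestShapes:
    def test_backbone_full_resolution(self, tiny_model, rng):
        f = tiny_model.backbone_forward(random_image(rng))
        assert f.shape == (1, tiny_model.cfg.base_width, 32, 32)

    def test_multiscale_strides(self, tiny_model, rng):
        f = tiny_model.backbone_forward(random_image(rng, 64, 64))
        d1, d2, u1, u2 = tiny_model.multiscale_extract(f)
        assert d1.shape[2:] == (32, 32)
        assert d2.shape[2:] == (16, 16)
        assert u1.shape[2:] == (64, 64)
        assert u2.shape[2:] == (64, 64)

    def test_fused_channels_contract(self, tiny_model, rng):
        f = tiny_model.backbone_forward(random_image(rng))
        out = tiny_model.multiscale_fuse(f, *tiny_model.multiscale_extract(f))
        assert out.shape[1] == tiny_model.cfg.fused_channels

    def test_head_and_mask_resolution(self, tiny_model, rng, scene_pair):
        out = tiny_model(random_image(rng, 48, 36))
        k = tiny_model.cfg.num_classes
        assert out.p_cls.shape == (1, k, 48, 36)
        assert out.s_obj.shape == (1, 1, 48, 36)
        assert out.b_map.shape == (1, 4, 48, 36)
        assert final_segmentation(out).shape == (1, 48, 36)

    def test_indivisible_input_suggests_padding(self, tiny_model, rng):
        with pytest.raises(ValueError, match="pad"):
            tiny_model.backbone_forward(rng.random((33, 32, 3)))

    def test_predict_pads_odd_sizes(self, tiny_model, rng):
        mask = tiny_model.predict(rng.random((35, 37, 3)))
        assert mask.shape == (35, 37)

    @pytest.mark.parametrize("up,down", [
        ("bilinear", "max_pool"),
        ("transposed_conv", "strided_conv"),
    ])
    def test_alternative_resampling_modes(self, up, down, rng):
        cfg = NetworkConfig(num_classes=3, base_width=8, backbone_depth=1,
                            fused_channels=16, channel_reduction_ratio=4,
                            upsample_mode=up, downsample_mode=down)
        out = MultiScaleAttentionNet(cfg)(random_image(rng))
        assert out.p_cls.shape == (1, 3, 32, 32)


class TestInvariants:
    def test_softmax_attention_objectness_ranges(self, tiny_model, rng):
        for _ in range(10):
            out = tiny_model(random_image(rng))
            np.testing.assert_allclose(out.p_cls.data.sum(axis=1), 1.0, atol=1e-5)
            a = out.attention
            assert 0 < a.a_spatial.data.min() and a.a_spatial.data.max() < 1
            assert 0 < a.a_channel.data.min() and a.a_channel.data.max() < 1
            assert 0 < out.s_obj.data.min() and out.s_obj.data.max() < 1

    def test_constant_feature_map_gives_constant_spatial_attention(self, tiny_model):
        f = Tensor(np.full((1, 16, 24, 24), 0.37, dtype=np.float32))
        a, _ = tiny_model.spatial_attention(f)
        np.testing.assert_allclose(a.data, a.data.flat[0], rtol=1e-5)

    def test_spatial_gate_shrinks_magnitudes(self, tiny_model, rng):
        f = tiny_model.backbone_forward(random_image(rng))
        _, gated = tiny_model.spatial_attention(f)
        assert (np.abs(gated.data) <= np.abs(f.data) + 1e-7).all()

    def test_zero_input_channel_attention_is_spatially_flat(self, tiny_model):
        z = Tensor(np.zeros((1, 16, 8, 8), dtype=np.float32))
        att, _ = tiny_model.channel_attention(z)
        np.testing.assert_allclose(att.v_avg.data, 0.0, atol=1e-7)
        np.testing.assert_allclose(att.v_max.data, 0.0, atol=1e-7)
        # closed form: sigmoid(fc2(relu(fc1(0))))
        h = np.maximum(tiny_model.fc1.bias.data, 0)
        want = 1 / (1 + np.exp(-(h @ tiny_model.fc2.weight.data
                                 + tiny_model.fc2.bias.data)))
        np.testing.assert_allclose(att.a_channel.data[0], want, atol=1e-6)

    def test_pooled_vectors_scale_with_channel(self, tiny_model, rng):
        x = np.abs(rng.random((1, 16, 8, 8))).astype(np.float32)
        att1, _ = tiny_model.channel_attention(Tensor(x))
        x2 = x.copy()
        x2[:, 3] *= 2.5
        att2, _ = tiny_model.channel_attention(Tensor(x2))
        assert att2.v_avg.data[0, 3] == pytest.approx(2.5 * att1.v_avg.data[0, 3], rel=1e-5)
        assert att2.v_max.data[0, 3] == pytest.approx(2.5 * att1.v_max.data[0, 3], rel=1e-5)
        np.testing.assert_allclose(att2.v_avg.data[0, :3], att1.v_avg.data[0, :3], rtol=1e-6)

    def test_forward_is_deterministic(self, tiny_model, rng):
        img = random_image(rng)
        o1 = tiny_model(img)
        o2 = tiny_model(img)
        np.testing.assert_array_equal(o1.p_cls.data, o2.p_cls.data)
        np.testing.assert_array_equal(o1.s_obj.data, o2.s_obj.data)
        np.testing.assert_array_equal(o1.b_map.data, o2.b_map.data)


class TestAblationHooks:
    def test_residual_toggle_changes_outputs(self, rng):
        kw = dict(num_classes=3, base_width=8, backbone_depth=2,
                  fused_channels=16, channel_reduction_ratio=4, init_seed=7)
        img = random_image(rng)
        with_res = MultiScaleAttentionNet(NetworkConfig(**kw))(img)
        without = MultiScaleAttentionNet(NetworkConfig(residual=False, **kw))(img)
        assert (with_res.p_cls.data != without.p_cls.data).any()

    def test_disable_multiscale_projects_backbone(self, rng):
        kw = dict(num_classes=3, base_width=8, backbone_depth=1,
                  fused_channels=8, channel_reduction_ratio=4, init_seed=7)
        img = random_image(rng)
        model = MultiScaleAttentionNet(NetworkConfig(disable_multiscale=True, **kw))
        # identity-initialised 1x1 projection: fusion becomes a pass-through
        model.proj_conv.weight.data = np.eye(8, dtype=np.float32).reshape(8, 8, 1, 1)
        model.proj_conv.bias.data[:] = 0
        f_yolo = model.backbone_forward(img)
        out = model(img)
        np.testing.assert_allclose(out.features["f_final"].data, f_yolo.data,
                                   rtol=1e-5, atol=1e-6)

    def test_disable_attention_passes_features_through(self, rng):
        kw = dict(num_classes=3, base_width=8, backbone_depth=1,
                  fused_channels=16, channel_reduction_ratio=4, init_seed=7)
        img = random_image(rng)
        out = MultiScaleAttentionNet(NetworkConfig(disable_attention=True, **kw))(img)
        assert out.attention.a_spatial is None
        np.testing.assert_array_equal(out.features["f_channel"].data,
                                      out.features["f_final"].data)


class TestGradientConnectivity:
    def test_all_parameters_reached_from_heads(self, tiny_cfg, rng):
        model = MultiScaleAttentionNet(tiny_cfg)
        out = model(random_image(rng))
        # random projections so the softmax simplex constraint cannot
        # cancel gradients identically
        loss = ((out.p_cls * Tensor(rng.normal(0, 1, out.p_cls.shape))).sum()
                + (out.s_obj * Tensor(rng.normal(0, 1, out.s_obj.shape))).sum()
                + (out.b_map * Tensor(rng.normal(0, 1, out.b_map.shape))).sum())
        loss.backward()
        for p in model.parameters():
            assert p.grad is not None
            assert np.isfinite(p.grad).all()
        for blk in model.blocks:
            assert np.abs(blk.c1.conv.weight.grad).max() > 0
        assert np.abs(model.stem.conv.weight.grad).max() > 0


class TestFinalSegmentation:
    @staticmethod
    def _heads(p, s):
        return HeadOutputs(p_cls=Tensor(p), s_obj=Tensor(s),
                           b_map=Tensor(np.zeros((1, 4) + p.shape[2:])))

    def test_full_objectness_one_hot_is_argmax(self, rng):
        p = np.zeros((1, 3, 2, 2), dtype=np.float32)
        labels = rng.integers(0, 3, (2, 2))
        for i in range(2):
            for j in range(2):
                p[0, labels[i, j], i, j] = 1
        s = np.ones((1, 1, 2, 2), dtype=np.float32)
        np.testing.assert_array_equal(final_segmentation(self._heads(p, s))[0], labels)

    def test_zero_objectness_is_all_background(self, rng):
        p = rng.dirichlet(np.ones(4), (2, 2)).transpose(2, 0, 1)[None].astype(np.float32)
        s = np.zeros((1, 1, 2, 2), dtype=np.float32)
        assert (final_segmentation(self._heads(p, s)) == 0).all()

    def test_mixed_scores_match_brute_force(self, rng):
        k = 4
        p = rng.dirichlet(np.ones(k), (2, 2)).transpose(2, 0, 1)[None].astype(np.float32)
        s = rng.random((1, 1, 2, 2)).astype(np.float32)
        got = final_segmentation(self._heads(p, s))[0]
        for i in range(2):
            for j in range(2):
                scores = [p[0, 0, i, j] * (1 - s[0, 0, i, j])] + [
                    p[0, c, i, j] * s[0, 0, i, j] for c in range(1, k)]
                assert got[i, j] == int(np.argmax(scores))


class TestDecodeBoxes:
    def test_single_confident_blob_gives_one_box(self):
        k = 3
        p = np.zeros((1, k, 16, 16), dtype=np.float32)
        p[0, 0] = 1.0
        s = np.full((1, 1, 16, 16), 0.01, dtype=np.float32)
        b = np.zeros((1, 4, 16, 16), dtype=np.float32)
        # confident region predicting class 2 with identical boxes
        p[0, :, 4:8, 4:8] = 0
        p[0, 2, 4:8, 4:8] = 1.0
        s[0, 0, 4:8, 4:8] = 0.9
        b[0, :, 4:8, 4:8] = np.array([0.35, 0.35, 0.25, 0.25])[:, None, None]
        out = decode_boxes(HeadOutputs(p_cls=Tensor(p), s_obj=Tensor(s), b_map=Tensor(b)))
        assert len(out) == 1
        assert out[0]["class_id"] == 2
        np.testing.assert_allclose(out[0]["box"], [0.35, 0.35, 0.25, 0.25], atol=1e-6)

    def test_no_boxes_below_threshold(self):
        p = np.full((1, 2, 8, 8), 0.5, dtype=np.float32)
        s = np.full((1, 1, 8, 8), 0.4, dtype=np.float32)
        b = np.zeros((1, 4, 8, 8), dtype=np.float32)
        assert decode_boxes(HeadOutputs(p_cls=Tensor(p), s_obj=Tensor(s),
                                        b_map=Tensor(b))) == []


class TestCheckpoint:
    def test_save_load_round_trip(self, tiny_cfg, rng, tmp_path):
        model = MultiScaleAttentionNet(tiny_cfg)
        img = random_image(rng)
        before = model(img).p_cls.data
        path = tmp_path / "ckpt.npz"
        model.save(path)
        reloaded = MultiScaleAttentionNet.load(path)
        assert reloaded.cfg == tiny_cfg
        np.testing.assert_array_equal(reloaded(img).p_cls.data, before)
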