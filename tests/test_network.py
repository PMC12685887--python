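"""End-to-end network assembly: shapes, fusion, pixel shuffle, skips."""

import dataclasses

import numpy as np
import pytest

from hffen.attention import ConfigError
from hffen.autograd import Tensor
from hffen.network import (
    HFFEN,
    EDSRBranch,
    HFFESRModule,
    NetworkConfig,
    SRBranch,
    pixel_shuffle,
)
from hffen.nn import DTYPE


def feats(rng, c, h, w, b=1):
    return Tensor(rng.normal(size=(b, c, h, w)).astype(DTYPE))


class TestShallowExtract:
    def test_shape_contract(self, tiny_cfg, rng):
        net = HFFEN(tiny_cfg, seed=0)
        out = net.shallow_extract(feats(rng, 3, 48, 48))
        assert out.shape == (1, tiny_cfg.channels, 48, 48)

    def test_wrong_channel_count_rejected(self, tiny_cfg, rng):
        net = HFFEN(tiny_cfg, seed=0)
        with pytest.raises(ValueError, match="3"):
            net.shallow_extract(feats(rng, 4, 8, 8))

    def test_biasfree_layer_is_linear_in_the_input(self, tiny_cfg, rng):
        net = HFFEN(tiny_cfg, seed=0)
        net.shallow.bias.data[:] = 0.0
        x = rng.normal(size=(1, 3, 8, 8)).astype(np.float64)
        y1 = net.shallow_extract(Tensor(x)).data
        y2 = net.shallow_extract(Tensor(2.0 * x)).data
        np.testing.assert_allclose(y2, 2.0 * y1, rtol=1e-10)
        y0 = net.shallow_extract(Tensor(np.zeros_like(x))).data
        np.testing.assert_array_equal(y0, 0.0)


class TestHFFESRModule:
    def test_fusion_is_sum_of_independently_evaluated_branches(self, tiny_cfg, rng):
        mod = HFFESRModule(tiny_cfg, np.random.default_rng(0))
        mod.hf_branch.gate.data[:] = 0.7  # open the injection gate
        x = feats(rng, tiny_cfg.channels, 12, 12)
        fused = mod(x).data
        separate = mod.sr_branch(x).data + mod.hf_branch(x).data
        np.testing.assert_allclose(fused, separate, atol=1e-6)

    def test_zeroed_hf_branch_reduces_to_backbone(self, tiny_cfg, rng):
        cfg = dataclasses.replace(tiny_cfg, use_hiem=False, use_ha=False)
        mod = HFFESRModule(cfg, np.random.default_rng(0))
        assert mod.hf_branch is None
        x = feats(rng, cfg.channels, 24, 24)
        np.testing.assert_array_equal(mod(x).data, mod.sr_branch(x).data)

    def test_shape_contract(self, tiny_cfg, rng):
        mod = HFFESRModule(tiny_cfg, np.random.default_rng(0))
        assert mod(feats(rng, tiny_cfg.channels, 24, 24)).shape == (
            1, tiny_cfg.channels, 24, 24,
        )

    def test_non_shape_preserving_backbone_rejected_at_construction(self, tiny_cfg):
        class Bad(SRBranch):
            def __init__(self):
                pass

            def forward(self, x):
                return x.crop2d(0, 0, x.shape[2] // 2, x.shape[3])

        with pytest.raises(ConfigError, match="shape-preserving"):
            HFFESRModule._probe(Bad(), tiny_cfg.channels)


class TestPixelShuffle:
    def test_index_mapping_matches_brute_force_enumeration(self):
        r = 2
        x = np.zeros((1, 4, 2, 2))
        for c in range(4):
            x[0, c] = c
        out = pixel_shuffle(Tensor(x), r).data
        expect = np.zeros((1, 1, 4, 4))
        for h in range(2):
            for w in range(2):
                for i in range(r):
                    for j in range(r):
                        expect[0, 0, h * r + i, w * r + j] = x[0, i * r + j, h, w]
        np.testing.assert_array_equal(out, expect)

    def test_element_count_is_conserved(self, rng):
        x = rng.normal(size=(2, 18, 5, 7))
        out = pixel_shuffle(Tensor(x), 3)
        assert out.data.size == x.size and out.shape == (2, 2, 15, 21)

    def test_values_are_a_permutation(self, rng):
        x = rng.normal(size=(1, 16, 3, 3))
        out = pixel_shuffle(Tensor(x), 4).data
        np.testing.assert_array_equal(np.sort(out.ravel()), np.sort(x.ravel()))


class TestForward:
    def test_output_is_exactly_scale_times_input(self, tiny_cfg):
        img = np.random.default_rng(0).integers(0, 256, (48, 48, 3), dtype=np.uint8)
        net = HFFEN(tiny_cfg, seed=0)
        assert net(img).shape == (96, 96, 3)

    def test_window_incompatible_sizes_are_padded_not_rejected(self, tiny_cfg):
        cfg = dataclasses.replace(tiny_cfg, scale=3)
        net = HFFEN(cfg, seed=0)
        img = np.random.default_rng(0).integers(0, 256, (41, 37, 3), dtype=np.uint8)
        assert net(img).shape == (123, 111, 3)

    @pytest.mark.parametrize("scale", [2, 3, 4])
    @pytest.mark.parametrize("hw", [(17, 32), (32, 48), (48, 17)])
    def test_exact_scale_contract_sweep(self, tiny_cfg, scale, hw):
        cfg = dataclasses.replace(tiny_cfg, scale=scale)
        net = HFFEN(cfg, seed=0)
        h, w = hw
        img = np.random.default_rng(1).integers(0, 256, (h, w, 3), dtype=np.uint8)
        assert net(img).shape == (scale * h, scale * w, 3)

    def test_inference_is_bit_deterministic(self, tiny_cfg):
        net = HFFEN(tiny_cfg, seed=0)
        img = np.random.default_rng(2).integers(0, 256, (20, 20, 3), dtype=np.uint8)
        np.testing.assert_array_equal(net(img), net(img))

    def test_x4_single_stage_shuffle_config(self, tiny_cfg):
        cfg = dataclasses.replace(tiny_cfg, scale=4, x4_two_stage=False)
        net = HFFEN(cfg, seed=0)
        img = np.random.default_rng(3).integers(0, 256, (16, 16, 3), dtype=np.uint8)
        assert net(img).shape == (64, 64, 3)

    def test_invalid_scale_rejected(self, tiny_cfg):
        with pytest.raises(ConfigError, match="scale"):
            dataclasses.replace(tiny_cfg, scale=5)


class TestPlugAndPlay:
    def test_disabled_branch_equals_bare_backbone_cascade(self, tiny_cfg, rng):
        """Functional meaning of plug-and-play: removing HF-FE leaves
        exactly the backbone cascade."""
        cfg = dataclasses.replace(tiny_cfg, use_hiem=False, use_ha=False)
        net = HFFEN(cfg, seed=0)
        for _ in range(50):
            x = Tensor(rng.normal(size=(1, 3, 14, 14)).astype(DTYPE))
            f0 = net.shallow_extract(x)
            f = f0
            for m in net.modules_:
                f = m.sr_branch(f)  # bare backbone, same weights
            bare = net.upsampler(net.agg(f) + f0).data
            full = net.forward_features(x).data
            np.testing.assert_array_equal(full, bare)

    def test_attached_branch_starts_functionally_identical_to_baseline(self, tiny_cfg, rng):
        """Zero-initialised injection gate + separate branch RNG: at
        construction, the full network computes exactly what the
        HF-FE-disabled network computes, weight for weight."""
        full = HFFEN(tiny_cfg, seed=11)
        base = HFFEN(
            dataclasses.replace(tiny_cfg, use_hiem=False, use_ha=False), seed=11
        )
        np.testing.assert_array_equal(
            full.shallow.weight.data, base.shallow.weight.data
        )
        np.testing.assert_array_equal(
            full.modules_[0].sr_branch.stack.blocks[0].conv1.weight.data,
            base.modules_[0].sr_branch.stack.blocks[0].conv1.weight.data,
        )
        for _ in range(5):
            img = np.random.default_rng(0).integers(0, 256, (20, 20, 3), dtype=np.uint8)
            np.testing.assert_array_equal(full(img), base(img))

    def test_global_skip_survives_zeroed_modules(self, tiny_cfg, rng):
        """With zeroed module/aggregation weights and bias-free convs the
        output reduces to upsample(F0): the shallow path survives."""
        net = HFFEN(tiny_cfg, seed=0)
        for name, p in net.named_parameters():
            if not name.startswith(("shallow", "upsampler")):
                p.data[:] = 0.0
        x = feats(rng, 3, 10, 10)
        f0 = net.shallow_extract(x)
        np.testing.assert_allclose(
            net.forward_features(x).data, net.upsampler(f0).data, atol=1e-7
        )

    def test_gradients_reach_both_ends_after_one_step(self, tiny_cfg, rng):
        """After one optimisation step the injection gate has opened, so
        gradients reach both the first conv and the deepest MLP."""
        from hffen.training import Adam, l1_loss

        net = HFFEN(tiny_cfg, seed=0)
        opt = Adam(net.parameters())
        x = feats(rng, 3, 12, 12)
        y = feats(rng, 3, 24, 24)
        for _ in range(2):
            loss = l1_loss(net.forward_features(x), y)
            net.zero_grad()
            loss.backward()
            opt.step(1e-3)
        g_first = np.linalg.norm(net.shallow.weight.grad)
        g_last_mlp = np.linalg.norm(net.modules_[0].hf_branch.ha.mlp_out.weight.grad)
        assert g_first > 0 and g_last_mlp > 0
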