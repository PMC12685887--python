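"""The Laplacian high-frequency stage and the HF-FE branch."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from hffen.attention import AttentionConfig, ConfigError
from hffen.autograd import Tensor
from hffen.blocks import (
    HFFEBranch,
    HiemConfig,
    LAPLACIAN_KERNELS,
    LaplacianSpec,
    ResidualStack,
    laplacian_filter,
)
from hffen.synthetic_plants import SceneSpec, generate_leaf


def brute_force_depthwise(x, kernel, padding):
    """Direct nested-loop valid convolution oracle on a padded array."""
    mode = {"reflect": "reflect", "zero": "constant"}[padding]
    xp = np.pad(x, [(0, 0), (0, 0), (1, 1), (1, 1)], mode=mode)
    B, C, H, W = x.shape
    out = np.zeros_like(x, dtype=float)
    for b in range(B):
        for c in range(C):
            for i in range(H):
                for j in range(W):
                    out[b, c, i, j] = (xp[b, c, i : i + 3, j : j + 3] * kernel).sum()
    return out


class TestLaplacianFilter:
    def test_constant_input_gives_exact_zero_at_any_channel_count(self):
        for name in ("lap4", "lap8"):
            spec = LaplacianSpec.from_name(name)
            for channels in (1, 3, 8):
                x = Tensor(np.full((1, channels, 8, 8), 5.0))
                out = laplacian_filter(x, spec)
                assert np.all(out.data == 0.0)

    def test_impulse_response_is_the_stencil(self):
        x = np.zeros((1, 1, 5, 5))
        x[0, 0, 2, 2] = 1.0
        out = laplacian_filter(Tensor(x), LaplacianSpec.from_name("lap4")).data
        np.testing.assert_array_equal(out[0, 0, 1:4, 1:4], LAPLACIAN_KERNELS["lap4"])

    def test_linear_ramp_vanishes_at_interior_pixels(self):
        xx = np.arange(9.0)[None, :].repeat(9, axis=0)
        out = laplacian_filter(Tensor(xx[None, None]), LaplacianSpec()).data
        np.testing.assert_allclose(out[0, 0, 1:-1, 1:-1], 0.0, atol=1e-12)

    @pytest.mark.parametrize("padding", ["reflect", "zero"])
    @pytest.mark.parametrize("kernel", ["lap4", "lap8"])
    def test_matches_brute_force_convolution_on_random_inputs(self, padding, kernel, rng):
        spec = LaplacianSpec.from_name(kernel, padding=padding)
        x = rng.normal(size=(2, 3, 7, 7))
        out = laplacian_filter(Tensor(x), spec).data
        ref = brute_force_depthwise(x, spec.kernel, padding)
        np.testing.assert_allclose(out, ref, atol=1e-10)

    def test_rejects_non_finite_input_naming_the_block(self):
        x = np.ones((1, 1, 4, 4))
        x[0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="laplacian_filter"):
            laplacian_filter(Tensor(x), LaplacianSpec())

    def test_spec_invariants_enforced(self):
        with pytest.raises(ConfigError, match="sum"):
            LaplacianSpec(kernel=np.ones((3, 3)))
        with pytest.raises(ConfigError, match="fixed"):
            LaplacianSpec(learnable=True)


class TestResidualRefine:
    def test_zero_initialised_residual_branch_is_the_identity(self, rng):
        stack = ResidualStack(6, depth=3, rng=rng)
        for blk in stack.blocks:
            blk.conv2.weight.data[:] = 0.0
            blk.conv2.bias.data[:] = 0.0
        x = rng.normal(size=(2, 6, 5, 5)).astype(np.float32)
        np.testing.assert_array_equal(stack(Tensor(x)).data, x)

    def test_shape_contract(self, rng):
        stack = ResidualStack(64, depth=4, rng=rng)
        out = stack(Tensor(rng.normal(size=(1, 64, 24, 24)).astype(np.float32)))
        assert out.shape == (1, 64, 24, 24)

    def test_depth_zero_is_a_configuration_error(self, rng):
        with pytest.raises(ConfigError):
            ResidualStack(8, depth=0, rng=rng)
        with pytest.raises(ConfigError):
            HiemConfig(depth=0)

    def test_finite_output_over_many_random_initialisations(self):
        x = np.random.default_rng(0).normal(size=(1, 4, 6, 6)).astype(np.float32)
        for seed in range(100):
            stack = ResidualStack(4, depth=2, rng=np.random.default_rng(seed))
            assert np.isfinite(stack(Tensor(x)).data).all()


class TestHFFEBranch:
    def _branch(self, channels, depth=2, seed=0, **ha_kw):
        return HFFEBranch(
            channels,
            HiemConfig(depth=depth),
            AttentionConfig(channels=channels, heads=2, ca_reduction=4, **ha_kw),
            np.random.default_rng(seed),
        )

    def test_shape_contract(self, rng):
        branch = self._branch(32)
        out = branch(Tensor(rng.normal(size=(1, 32, 16, 16)).astype(np.float32)))
        assert out.shape == (1, 32, 16, 16)

    def test_channel_mismatch_is_a_configuration_error(self, rng):
        with pytest.raises(ConfigError, match="channels"):
            HFFEBranch(
                16,
                HiemConfig(),
                AttentionConfig(channels=8, heads=2),
                np.random.default_rng(0),
            )
        branch = self._branch(16)
        with pytest.raises(ConfigError):
            branch(Tensor(np.zeros((1, 8, 8, 8), dtype=np.float32)))

    def test_constant_input_with_zeroed_biasfree_tail_maps_to_zero(self):
        branch = HFFEBranch(
            8,
            HiemConfig(depth=1),
            AttentionConfig(channels=8, heads=2, ca_reduction=4, residual_skip=False),
            np.random.default_rng(0),
        )
        branch.gate.data[:] = 1.0  # open the injection gate; zeros must come
        # from the stages themselves:
        # zero-response tail: residual branch convs zeroed, HA projections zeroed
        for blk in branch.refine.blocks:
            blk.conv2.weight.data[:] = 0.0
            blk.conv2.bias.data[:] = 0.0
        ha = branch.ha
        ha.msa.proj.weight.data[:] = 0.0
        ha.msa.proj.bias.data[:] = 0.0
        ha.ca.fc2.weight.data[:] = 0.0
        ha.ca.fc2.bias.data[:] = 0.0
        ha.mlp_out.weight.data[:] = 0.0
        ha.mlp_out.bias.data[:] = 0.0
        x = Tensor(np.full((1, 8, 8, 8), 3.0, dtype=np.float32))
        out = branch(x)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-7)

    @pytest.mark.parametrize("channels", [8, 16, 64])
    @pytest.mark.parametrize("depth", [1, 2, 4])
    def test_shape_and_finiteness_config_sweep(self, channels, depth, rng):
        branch = HFFEBranch(
            channels,
            HiemConfig(depth=depth),
            AttentionConfig(channels=channels, heads=2, ca_reduction=4),
            np.random.default_rng(channels + depth),
        )
        x = Tensor(rng.normal(size=(1, channels, 9, 9)).astype(np.float32))
        out = branch(x)
        assert out.shape == x.shape
        assert np.isfinite(out.data).all()

    def test_laplacian_stage_responds_more_to_venation_than_to_blur(self):
        img = generate_leaf(SceneSpec(seed=4, venation_density=0.9)).mean(axis=-1)
        blurred = gaussian_filter(img, 3.0)
        spec = LaplacianSpec()
        r_sharp = laplacian_filter(Tensor(img[None, None] / 255.0), spec).data
        r_blur = laplacian_filter(Tensor(blurred[None, None] / 255.0), spec).data
        assert np.abs(r_sharp).mean() > np.abs(r_blur).mean()
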