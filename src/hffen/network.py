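"""HFFEN: the end-to-end high-frequency feature-enhancement SR network.

Pipeline (all feature maps C x H x W at the LR spatial size until the
upsampler):

    F_0 = conv3x3(I_LR)                         shallow feature extraction
    F_n = SR(F_{n-1}) + HF-FE(F_{n-1})          n = 1..N, parallel branches
    F_D = conv3x3(F_N)                          aggregation
    I_SR = upsample(F_D + F_0)                  global skip + pixel shuffle

The SR branch is *pluggable*: any shape-preserving trainable map C x H x W ->
C x H x W satisfies :class:`SRBranch`; the shipped reference branch is a
stack of EDSR-style residual blocks. Disabling the HF-FE branch reduces every
module to its bare backbone — the testable meaning of "plug-and-play".

Pixel intensities are normalised to [0, 1] by dividing by 255 (no mean
shift); outputs are clamped to the valid range only at inference, never
during loss computation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .attention import AttentionConfig, ConfigError
from .autograd import Tensor, no_grad
from .blocks import HFFEBranch, HiemConfig

VALID_SCALES = (2, 3, 4)


@dataclass
class NetworkConfig:
    """All architectural free parameters.

    channels:        feature width C.
    n_modules:       number N of cascaded HF-FE + SR modules.
    scale:           upscaling factor; one model per scale (2, 3 or 4).
    backbone:        identifier of the SR-branch implementation.
    backbone_blocks: residual blocks per SR branch (reference backbone).
    use_hiem/use_ha: ablation switches for the two HF-FE stages; with both
                     off the HF-FE branch disappears entirely (baseline).
    x4_two_stage:    realise x4 as two x2 pixel-shuffle stages (default)
                     instead of a single x4 shuffle.
    """

    channels: int = 64
    n_modules: int = 4
    scale: int = 2
    backbone: str = "edsr"
    backbone_blocks: int = 16
    use_hiem: bool = True
    use_ha: bool = True
    x4_two_stage: bool = True
    hiem: HiemConfig = field(default_factory=HiemConfig)
    ha: AttentionConfig | None = None

    def __post_init__(self):
        if self.scale not in VALID_SCALES:
            raise ConfigError(f"scale must be one of {VALID_SCALES}, got {self.scale}")
        if self.n_modules < 1 or self.channels < 1:
            raise ConfigError("n_modules and channels must be positive")
        if isinstance(self.hiem, dict):
            self.hiem = HiemConfig(**self.hiem)
        if isinstance(self.ha, dict):
            d = dict(self.ha)
            if "window" in d:  # config-file key for the spatial window
                d["spatial_window"] = d.pop("window")
            self.ha = AttentionConfig(**d)
        if self.ha is None:
            self.ha = AttentionConfig(channels=self.channels)
        if self.ha.channels != self.channels:
            raise ConfigError(
                f"ha.channels ({self.ha.channels}) != network channels ({self.channels})"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)


class SRBranch(nn.Module):
    """Contract for a pluggable SR pathway: trainable, consumes a (B, C, H, W)
    feature map and returns one of identical shape (no internal re-scaling)."""

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - interface
        raise NotImplementedError


class EDSRBranch(SRBranch):
    """Reference SR branch: a stack of full-width EDSR-style residual blocks."""

    def __init__(self, channels: int, blocks: int, rng: np.random.Generator):
        from .blocks import ResidualStack

        self.stack = ResidualStack(channels, blocks, rng, bottleneck=1)

    def forward(self, x: Tensor) -> Tensor:
        return self.stack(x)


BACKBONES = {
    "edsr": lambda cfg, rng: EDSRBranch(cfg.channels, cfg.backbone_blocks, rng),
}


def pixel_shuffle(x: Tensor, r: int) -> Tensor:
    """Rearrange (B, C*r^2, H, W) -> (B, C, H*r, W*r).

    out[b, c, h*r + i, w*r + j] = in[b, c*r^2 + i*r + j, h, w]
    """
    B, Cr2, H, W = x.shape
    if Cr2 % (r * r) != 0:
        raise ConfigError(f"cannot shuffle {Cr2} channels by factor {r}")
    C = Cr2 // (r * r)
    return (
        x.reshape(B, C, r, r, H, W).transpose((0, 1, 4, 2, 5, 3)).reshape(B, C, H * r, W * r)
    )


class HFFESRModule(nn.Module):
    """One cascaded module: F_n = SR(F_{n-1}) + HF-FE(F_{n-1}).

    Both branches read the same input in parallel; fusion is element-wise
    summation. With the HF-FE branch disabled, F_n is the backbone output.
    """

    def __init__(
        self,
        cfg: NetworkConfig,
        rng: np.random.Generator,
        rng_hf: np.random.Generator | None = None,
    ):
        if cfg.backbone not in BACKBONES:
            raise ConfigError(f"unknown backbone {cfg.backbone!r}")
        self.sr_branch = BACKBONES[cfg.backbone](cfg, rng)
        self._probe(self.sr_branch, cfg.channels)
        # the branch draws from its own generator so the backbone weights are
        # identical whether or not the HF-FE branch is attached
        self.hf_branch = (
            HFFEBranch(
                cfg.channels, cfg.hiem, cfg.ha, rng_hf if rng_hf is not None else rng,
                use_hiem=cfg.use_hiem, use_ha=cfg.use_ha,
            )
            if (cfg.use_hiem or cfg.use_ha)
            else None
        )

    @staticmethod
    def _probe(branch: SRBranch, channels: int):
        """Structural check: the SR branch must preserve shape."""
        x = Tensor(np.zeros((1, channels, 8, 8), dtype=nn.DTYPE))
        with no_grad():
            y = branch(x)
        if y.shape != x.shape:
            raise ConfigError(
                f"SR branch violates the shape-preserving contract: "
                f"{x.shape} -> {y.shape}"
            )

    def forward(self, x: Tensor) -> Tensor:
        f_sr = self.sr_branch(x)
        if self.hf_branch is None:
            return f_sr
        return f_sr + self.hf_branch(x)


def _icnr(conv: nn.Conv2d, r: int, rng: np.random.Generator):
    """ICNR initialisation: the r^2 sub-kernels of each shuffle group start
    identical, so the pixel shuffle begins as a nearest-neighbour upsample
    (no checkerboard artifacts, much faster early convergence)."""
    C = conv.in_ch
    base = nn.kaiming(rng, (conv.out_ch // (r * r), C, conv.ksize, conv.ksize), C * conv.ksize**2)
    conv.weight.data = np.repeat(base, r * r, axis=0)


class Upsampler(nn.Module):
    """conv -> pixel shuffle (once, or two x2 stages for x4) -> conv to RGB."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        C, s = cfg.channels, cfg.scale
        if s == 4 and cfg.x4_two_stage:
            self.stages = nn.ModuleList(
                [nn.Conv2d(C, C * 4, 3, rng), nn.Conv2d(C, C * 4, 3, rng)]
            )
            self.factors = [2, 2]
        else:
            self.stages = nn.ModuleList([nn.Conv2d(C, C * s * s, 3, rng)])
            self.factors = [s]
        for conv, r in zip(self.stages, self.factors):
            _icnr(conv, r, rng)
        self.out_conv = nn.Conv2d(C, 3, 3, rng)
        # start near a constant mid-gray output: small (not zero) final
        # weights keep gradients flowing while avoiding the large random
        # initial reconstruction that wastes early iterations
        self.out_conv.weight.data *= 0.01
        self.out_conv.bias.data[:] = 0.5

    def forward(self, x: Tensor) -> Tensor:
        for conv, r in zip(self.stages, self.factors):
            x = pixel_shuffle(conv(x), r)
        return self.out_conv(x)


class HFFEN(nn.Module):
    """The full network. Built from a :class:`NetworkConfig` and a seed."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        rng_hf = np.random.default_rng([seed, 104729])
        C = cfg.channels
        self.shallow = nn.Conv2d(3, C, 3, rng)
        self.modules_ = nn.ModuleList(
            HFFESRModule(cfg, rng, rng_hf) for _ in range(cfg.n_modules)
        )
        self.agg = nn.Conv2d(C, C, 3, rng)
        self.upsampler = Upsampler(cfg, rng)

    # -- spec operations ------------------------------------------------------

    def shallow_extract(self, lr: Tensor) -> Tensor:
        """F_0 = conv3x3(I_LR); input must be a 3-channel normalised map."""
        if lr.ndim != 4 or lr.shape[1] != 3:
            raise ValueError(f"expected a (B, 3, H, W) input, got {lr.shape}")
        return self.shallow(lr)

    def reconstruct(self, f_deep: Tensor, f0: Tensor) -> Tensor:
        """I_SR = upsample(F_D + F_0); exact scale-factor output size."""
        if f_deep.shape != f0.shape:
            raise ConfigError(
                f"aggregated features {f_deep.shape} do not match shallow features {f0.shape}"
            )
        return self.upsampler(f_deep + f0)

    def forward_features(self, lr: Tensor) -> Tensor:
        """Full differentiable pipeline on a normalised (B, 3, H, W) map.

        Returns the unclamped (B, 3, sH, sW) reconstruction in [0, 1] units.
        """
        f0 = self.shallow_extract(lr)
        f = f0
        for m in self.modules_:
            f = m(f)
        return self.reconstruct(self.agg(f), f0)

    def forward(self, img_u8: np.ndarray) -> np.ndarray:
        """Inference on one 8-bit RGB image (H, W, 3) -> (sH, sW, 3) uint8.

        Deterministic: no stochastic layers; attention pads internally, so
        any input size is accepted and the output is exactly scale x input.
        """
        img_u8 = np.asarray(img_u8)
        if img_u8.ndim != 3 or img_u8.shape[2] != 3:
            raise ValueError(f"expected an (H, W, 3) RGB image, got {img_u8.shape}")
        x = Tensor(
            (img_u8.astype(np.float32) / 255.0).transpose(2, 0, 1)[None]
        )
        with no_grad():
            y = self.forward_features(x)
        out = np.clip(y.data[0].transpose(1, 2, 0), 0.0, 1.0) * 255.0
        return np.rint(out).astype(np.uint8)
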