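"""High-frequency enhancement blocks (HIEM) and the composite HF-FE branch.

The branch implements  HF-FE(x) = HA(R(L * x)):

* ``L`` — a fixed, non-learnable Laplacian stencil applied depthwise (each
  channel filtered independently, no cross-channel mixing). Its entries sum
  to zero, so any constant (DC) component is annihilated and only edge/texture
  structure survives.
* ``R`` — a stack of residual blocks refining the raw high-pass response.
  Each block is conv3x3 -> ReLU -> conv3x3 with an additive skip; the two
  convs bottleneck to C/`bottleneck` internal channels so the whole branch
  stays a small fraction of the backbone's cost.
* ``HA`` — the hybrid spatial/channel attention unit (:mod:`hffen.attention`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .attention import AttentionConfig, ConfigError, HybridAttention
from .autograd import Tensor

LAPLACIAN_KERNELS = {
    # canonical 4-neighbour discrete Laplacian
    "lap4": np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]]),
    # 8-neighbour variant
    "lap8": np.array([[1.0, 1.0, 1.0], [1.0, -8.0, 1.0], [1.0, 1.0, 1.0]]),
}


@dataclass
class LaplacianSpec:
    """A fixed 3x3 high-pass stencil.

    The kernel must sum to zero (zero DC response) and is never trained:
    it is stored as a plain array, invisible to the optimizer.
    """

    kernel: np.ndarray = field(default_factory=lambda: LAPLACIAN_KERNELS["lap4"].copy())
    per_channel: bool = True
    learnable: bool = False
    padding: str = "reflect"

    @classmethod
    def from_name(cls, name: str, padding: str = "reflect") -> "LaplacianSpec":
        if name not in LAPLACIAN_KERNELS:
            raise ConfigError(f"unknown Laplacian kernel {name!r}; choose lap4|lap8")
        return cls(kernel=LAPLACIAN_KERNELS[name].copy(), padding=padding)

    def __post_init__(self):
        self.kernel = np.asarray(self.kernel, dtype=np.float64)
        if self.kernel.shape != (3, 3):
            raise ConfigError("Laplacian kernel must be 3x3")
        if self.kernel.sum() != 0.0:
            raise ConfigError("Laplacian kernel entries must sum to exactly 0")
        if self.learnable:
            raise ConfigError("the Laplacian filter is fixed; learnable=True is invalid")
        if not self.per_channel:
            raise ConfigError("the Laplacian is applied depthwise; per_channel must be True")
        if self.padding not in ("reflect", "zero"):
            raise ConfigError(f"unknown padding {self.padding!r}; choose reflect|zero")


@dataclass
class HiemConfig:
    """Configuration of the Laplacian + residual-refinement stage."""

    kernel: str = "lap4"
    depth: int = 4
    padding: str = "reflect"
    bottleneck: int = 4

    def __post_init__(self):
        if self.depth < 1:
            raise ConfigError(
                "hiem.depth must be >= 1 (disable the branch instead of using depth 0)"
            )
        if self.bottleneck < 1:
            raise ConfigError("hiem.bottleneck must be >= 1")

    def laplacian_spec(self) -> LaplacianSpec:
        return LaplacianSpec.from_name(self.kernel, padding=self.padding)


def _check_finite(x: Tensor, where: str):
    if not np.isfinite(x.data).all():
        raise ValueError(f"non-finite activations entering {where}")


def laplacian_filter(x: Tensor, spec: LaplacianSpec) -> Tensor:
    """Depthwise 2-D convolution of every channel with the fixed stencil.

    Shape-preserving; padding mode comes from the spec. Rejects non-finite
    input with a diagnostic naming this block.
    """
    _check_finite(x, "laplacian_filter")
    if x.ndim != 4 or x.shape[1] < 1:
        raise ValueError("laplacian_filter expects a (B, C, H, W) map with C >= 1")
    return x.pad2d(1, mode=spec.padding).depthwise_conv2d(spec.kernel)


class ResidualBlock(nn.Module):
    """conv3x3 -> ReLU -> conv3x3 with additive skip; internal bottleneck width."""

    def __init__(
        self,
        channels: int,
        rng: np.random.Generator,
        bottleneck: int = 1,
        padding: str = "reflect",
    ):
        inner = max(1, channels // bottleneck)
        self.conv1 = nn.Conv2d(channels, inner, 3, rng, padding=padding)
        self.conv2 = nn.Conv2d(inner, channels, 3, rng, padding=padding)

    def forward(self, x: Tensor) -> Tensor:
        return x + self.conv2(self.conv1(x).relu())


class ResidualStack(nn.Module):
    """`depth` residual blocks in sequence (the R(.) operator)."""

    def __init__(
        self,
        channels: int,
        depth: int,
        rng: np.random.Generator,
        bottleneck: int = 1,
        padding: str = "reflect",
    ):
        if depth < 1:
            raise ConfigError("residual stack depth must be >= 1")
        self.blocks = nn.ModuleList(
            ResidualBlock(channels, rng, bottleneck=bottleneck, padding=padding)
            for _ in range(depth)
        )

    def forward(self, x: Tensor) -> Tensor:
        for b in self.blocks:
            x = b(x)
        return x


def residual_refine(x: Tensor, stack: ResidualStack) -> Tensor:
    """Apply a residual stack; shape-preserving."""
    _check_finite(x, "residual_refine")
    return stack(x)


class HFFEBranch(nn.Module):
    """The full high-frequency feature-enhancement branch HA(R(L*x)).

    `use_hiem` / `use_ha` switch the two stages independently (for the
    ablation variants); switching one off replaces it with the identity.

    The branch output is scaled by a learnable scalar gate initialised to
    zero (ReZero-style): a network with the branch attached starts
    functionally identical to the bare backbone and opens the high-frequency
    pathway only where it reduces the loss. This is the standard way to
    inject a new branch into a working backbone without destabilising it.
    """

    def __init__(
        self,
        channels: int,
        hiem: HiemConfig,
        ha: AttentionConfig,
        rng: np.random.Generator,
        use_hiem: bool = True,
        use_ha: bool = True,
    ):
        if use_ha and ha.channels != channels:
            raise ConfigError(
                f"HA configured for {ha.channels} channels but branch carries {channels}"
            )
        self.channels = channels
        self.use_hiem = use_hiem
        self.use_ha = use_ha
        self.lap_spec = hiem.laplacian_spec() if use_hiem else None
        self.refine = (
            ResidualStack(
                channels, hiem.depth, rng, bottleneck=hiem.bottleneck, padding=hiem.padding
            )
            if use_hiem
            else None
        )
        self.ha = HybridAttention(ha, rng) if use_ha else None
        self.gate = nn.Parameter(np.zeros(1))

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ConfigError(
                f"branch built for {self.channels} channels, got {x.shape[1]}"
            )
        _check_finite(x, "hf_fe_branch")
        out = x
        if self.use_hiem:
            out = residual_refine(laplacian_filter(out, self.lap_spec), self.refine)
        if self.use_ha:
            out = self.ha(out)
        return out * self.gate


def hf_fe_branch(x: Tensor, branch: HFFEBranch) -> Tensor:
    """Functional entry point: composition order is exactly L -> R -> HA."""
    return branch(x)
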