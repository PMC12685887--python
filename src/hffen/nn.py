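"""Minimal neural-network layer library over :mod:`hffen.autograd`.

Layers own :class:`Parameter` tensors, know how to enumerate them for the
optimizer, and implement `forward`. Weight initialisation is explicit: every
layer takes a `numpy.random.Generator`, so a network built from one seed is
bit-reproducible.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

DTYPE = np.float32


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)


class Module:
    """Base class: parameter discovery via attribute walk."""

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(full + ".")
            elif isinstance(value, ModuleList):
                for i, m in enumerate(value):
                    yield from m.named_parameters(f"{full}.{i}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, ModuleList):
                for i, m in enumerate(value):
                    yield f"{name}.{i}", m

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"checkpoint missing parameters: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}"
                )
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(list):
    """A list of modules that participates in parameter discovery."""


def kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    """He-normal initialisation for ReLU-family layers."""
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(DTYPE)


class Conv2d(Module):
    """3x3 (or kxk) stride-1 convolution with same-size output.

    `padding` is 'reflect' (default, avoids dark halos from edge filters) or
    'zero'. 1x1 convolutions skip padding entirely.
    """

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        ksize: int,
        rng: np.random.Generator,
        padding: str = "reflect",
        bias: bool = True,
    ):
        if ksize % 2 != 1:
            raise ValueError("only odd kernel sizes are supported")
        self.in_ch, self.out_ch, self.ksize = in_ch, out_ch, ksize
        self.padding = padding
        fan_in = in_ch * ksize * ksize
        self.weight = Parameter(kaiming(rng, (out_ch, in_ch, ksize, ksize), fan_in))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        pad = self.ksize // 2
        if pad:
            x = x.pad2d(pad, mode=self.padding)
        return x.conv2d(self.weight, self.bias)


class Linear(Module):
    def __init__(self, din: int, dout: int, rng: np.random.Generator, bias: bool = True):
        self.din, self.dout = din, dout
        self.weight = Parameter(kaiming(rng, (din, dout), din))
        self.bias = Parameter(np.zeros(dout)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    """Channel-wise layer normalisation for (B, C, H, W) feature maps."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.channels = channels
        self.eps = eps
        self.gamma = Parameter(np.ones((1, channels, 1, 1)))
        self.beta = Parameter(np.zeros((1, channels, 1, 1)))

    def forward(self, x: Tensor) -> Tensor:
        return x.layer_norm(self.gamma, self.beta, axis=1, eps=self.eps)
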