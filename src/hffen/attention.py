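"""Hybrid attention (HA): parallel multi-head self-attention and channel
attention, summed, normalised, and passed through a lightweight MLP.

The two paths read the *same* input (they are parallel, not sequential):

    F_HA  = MSA(F_in) + CA(F_in)
    F_out = MLP(Norm(F_HA))            (+ F_in when the residual skip is on)

MSA attends over spatial positions (tokens of dimension C); for maps larger
than the configured window it runs on non-overlapping square windows to keep
the quadratic cost bounded. CA is squeeze-and-excitation-style per-channel
gating from globally pooled descriptors. No positional encoding is used, so
full (un-windowed) attention is exactly translation-equivariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .autograd import Tensor


class ConfigError(ValueError):
    """An attention/network configuration violates its invariants."""


@dataclass
class AttentionConfig:
    """Free parameters of one hybrid-attention unit.

    channels:      feature width C of the incoming map.
    heads:         number of self-attention heads (must divide channels).
    ca_reduction:  bottleneck divisor of the channel-attention MLP.
    mlp_expansion: hidden-width multiplier of the output MLP.
    spatial_window: side of the square attention window, or "full".
    residual_skip: add the unit input to the MLP output.
    """

    channels: int
    heads: int = 4
    ca_reduction: int = 16
    mlp_expansion: float = 2.0
    spatial_window: int | str = 8
    residual_skip: bool = True

    def __post_init__(self):
        if self.channels < 1 or self.heads < 1:
            raise ConfigError("channels and heads must be positive")
        if self.channels % self.heads != 0:
            raise ConfigError(
                f"channels ({self.channels}) not divisible by heads ({self.heads})"
            )
        if self.channels // max(self.ca_reduction, 1) < 1 or self.ca_reduction < 1:
            raise ConfigError("channels / ca_reduction must be >= 1")
        if self.spatial_window != "full" and int(self.spatial_window) < 1:
            raise ConfigError("spatial_window must be positive or 'full'")


class MultiHeadSelfAttention(nn.Module):
    """Window (or full) multi-head self-attention over spatial positions."""

    def __init__(self, cfg: AttentionConfig, rng: np.random.Generator):
        self.cfg = cfg
        C = cfg.channels
        self.qkv = nn.Linear(C, 3 * C, rng)
        self.proj = nn.Linear(C, C, rng)
        self.last_weights: np.ndarray | None = None  # (B', heads, T, T), inspection only

    def _window(self, H: int, W: int) -> int | None:
        w = self.cfg.spatial_window
        if w == "full" or (H <= int(w) and W <= int(w)):
            return None  # attend over the whole map
        return int(w)

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        if C != self.cfg.channels:
            raise ConfigError(f"input has {C} channels, attention expects {self.cfg.channels}")
        w = self._window(H, W)
        if w is None:
            tokens = x.reshape(B, C, H * W).transpose((0, 2, 1))  # (B, T, C)
            out = self._attend(tokens)
            return out.transpose((0, 2, 1)).reshape(B, C, H, W)
        pb, pr = (-H) % w, (-W) % w
        xp = x.pad2d((0, pb, 0, pr), mode="reflect")
        Hp, Wp = H + pb, W + pr
        nh, nw = Hp // w, Wp // w
        # (B, C, nh, w, nw, w) -> (B, nh, nw, w, w, C) -> (B*nh*nw, w*w, C)
        t = xp.reshape(B, C, nh, w, nw, w).transpose((0, 2, 4, 3, 5, 1))
        tokens = t.reshape(B * nh * nw, w * w, C)
        out = self._attend(tokens)
        out = (
            out.reshape(B, nh, nw, w, w, C)
            .transpose((0, 5, 1, 3, 2, 4))
            .reshape(B, C, Hp, Wp)
        )
        return out.crop2d(0, 0, H, W) if (pb or pr) else out

    def _attend(self, tokens: Tensor) -> Tensor:
        Bp, T, C = tokens.shape
        h = self.cfg.heads
        d = C // h
        qkv = self.qkv(tokens)  # (B', T, 3C)
        qkv = qkv.reshape(Bp, T, 3, h, d).transpose((2, 0, 3, 1, 4))  # (3, B', h, T, d)
        q = _take0(qkv, 0)
        k = _take0(qkv, 1)
        v = _take0(qkv, 2)
        scores = (q @ k.transpose((0, 1, 3, 2))) * (1.0 / np.sqrt(d))
        attn = scores.softmax(axis=-1)  # rows are convex weights per query
        self.last_weights = np.asarray(attn.data)
        out = attn @ v  # (B', h, T, d)
        out = out.transpose((0, 2, 1, 3)).reshape(Bp, T, C)
        return self.proj(out)


def _take0(t: Tensor, i: int) -> Tensor:
    """Differentiable selection t[i] along the first axis."""
    out_shape = t.shape[1:]

    def bw(g):
        if t.requires_grad:
            gx = np.zeros_like(t.data)
            gx[i] = g
            t._accum(gx)

    return Tensor._make(t.data[i].copy(), (t,), bw)


class ChannelAttention(nn.Module):
    """Per-channel sigmoid gating from globally average-pooled descriptors."""

    def __init__(self, cfg: AttentionConfig, rng: np.random.Generator):
        self.cfg = cfg
        C = cfg.channels
        hidden = max(1, C // cfg.ca_reduction)
        self.fc1 = nn.Linear(C, hidden, rng)
        self.fc2 = nn.Linear(hidden, C, rng)

    def gates(self, x: Tensor) -> Tensor:
        pooled = x.mean(axis=(2, 3))  # (B, C)
        return self.fc2(self.fc1(pooled).relu()).sigmoid()  # in (0, 1)

    def forward(self, x: Tensor) -> Tensor:
        B, C, _, _ = x.shape
        if C != self.cfg.channels:
            raise ConfigError(f"input has {C} channels, attention expects {self.cfg.channels}")
        g = self.gates(x).reshape(B, C, 1, 1)
        return x * g


class HybridAttention(nn.Module):
    """MSA and CA in parallel on the same input, fused by summation, then
    channel layer-norm and a two-layer 1x1-conv MLP."""

    def __init__(self, cfg: AttentionConfig, rng: np.random.Generator):
        self.cfg = cfg
        C = cfg.channels
        hidden = max(1, int(round(C * cfg.mlp_expansion)))
        self.msa = MultiHeadSelfAttention(cfg, rng)
        self.ca = ChannelAttention(cfg, rng)
        self.norm = nn.LayerNorm(C)
        self.mlp_in = nn.Conv2d(C, hidden, 1, rng)
        self.mlp_out = nn.Conv2d(hidden, C, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        fha = self.msa(x) + self.ca(x)
        out = self.mlp_out(self.mlp_in(self.norm(fha)).gelu())
        return x + out if self.cfg.residual_skip else out
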