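"""Evaluation: Y-channel PSNR/SSIM, the split-averaged metric report, and the
analytic parameter/multiply-add complexity counter.

Conventions (pinned in every report):

* Y channel — ITU-R BT.601 studio range by default
  (Y = 16 + 65.481 R' + 128.553 G' + 24.966 B', primed values in [0, 1]);
  a full-range variant is selectable.
* PSNR — 10 log10(peak^2 / MSE) in dB with peak 255 on the Y plane;
  identical inputs yield the infinite sentinel, which split averaging skips
  with a logged count rather than capping.
* SSIM — mean local SSIM with an 11x11 Gaussian window (sd 1.5),
  C1 = (0.01 peak)^2, C2 = (0.03 peak)^2, population (not sample)
  covariance; the half-window border is cropped before averaging.
* A border of `scale` pixels is cropped from each side before comparing,
  standard SR practice.

FLOPs are *theoretical* multiply-add counts derived symbolically from the
architecture (conv: k^2 Cin Cout Hout Wout; linear: din dout tokens;
attention: QKV/projection plus score and weighted-sum matmuls). Elementwise
additions, normalisations and activations are not counted. A layer type the
counter does not know raises, never silently omits.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from . import nn
from .attention import ChannelAttention, HybridAttention, MultiHeadSelfAttention
from .blocks import HFFEBranch, ResidualBlock, ResidualStack
from .degradation import bicubic_downsample
from .network import HFFEN, EDSRBranch, HFFESRModule, Upsampler

Y_CONVENTIONS = ("bt601-studio", "bt601-full")


def rgb_to_y(img: np.ndarray, convention: str = "bt601-studio") -> np.ndarray:
    """Luma plane of an 8-bit RGB image as float64."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got {img.shape}")
    r, g, b = (img[..., i].astype(np.float64) for i in range(3))
    if convention == "bt601-studio":
        return 16.0 + (65.481 * r + 128.553 * g + 24.966 * b) / 255.0
    if convention == "bt601-full":
        return 0.299 * r + 0.587 * g + 0.114 * b
    raise ValueError(f"unknown Y convention {convention!r}; choose {Y_CONVENTIONS}")


def psnr(a: np.ndarray, b: np.ndarray, peak: float = 255.0) -> float:
    """10 log10(peak^2 / MSE); +inf for identical inputs."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if peak <= 0:
        raise ValueError("peak must be positive")
    mse = float(((a - b) ** 2).mean())
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(peak * peak / mse)


SSIM_WIN = 11
SSIM_SIGMA = 1.5


def ssim(a: np.ndarray, b: np.ndarray, peak: float = 255.0) -> float:
    """Mean local SSIM, Gaussian-weighted (sd 1.5, 11x11 support)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if min(a.shape) < SSIM_WIN:
        raise ValueError(f"images must be at least {SSIM_WIN} px per side for SSIM")
    c1 = (0.01 * peak) ** 2
    c2 = (0.03 * peak) ** 2
    # truncate chosen so the Gaussian support is exactly the 11x11 window
    filt = lambda x: gaussian_filter(x, SSIM_SIGMA, truncate=3.5)
    ua, ub = filt(a), filt(b)
    vaa = filt(a * a) - ua * ua
    vbb = filt(b * b) - ub * ub
    vab = filt(a * b) - ua * ub
    s = ((2 * ua * ub + c1) * (2 * vab + c2)) / ((ua * ua + ub * ub + c1) * (vaa + vbb + c2))
    pad = (SSIM_WIN - 1) // 2
    return float(s[pad:-pad, pad:-pad].mean())


# ---------------------------------------------------------------------------
# metric report
# ---------------------------------------------------------------------------

@dataclass
class MetricReport:
    per_image: list  # (id, psnr_db, ssim)
    mean_psnr_db: float
    mean_ssim: float
    scale: int
    n_images: int
    skipped_psnr_sentinels: int = 0
    conventions: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "conventions": self.conventions,
                "scale": self.scale,
                "n_images": self.n_images,
                "mean_psnr_db": self.mean_psnr_db,
                "mean_ssim": self.mean_ssim,
                "skipped_psnr_sentinels": self.skipped_psnr_sentinels,
                "per_image": [
                    {"id": i, "psnr_db": p, "ssim": s} for i, p, s in self.per_image
                ],
            },
            indent=1,
            default=str,
        )

    def to_csv(self) -> str:
        head = "# " + json.dumps(self.conventions) + "\nid,psnr_db,ssim\n"
        rows = "".join(f"{i},{p},{s}\n" for i, p, s in self.per_image)
        return head + rows


def aggregate(per_image: list, scale: int, conventions: dict) -> MetricReport:
    finite = [p for _, p, _ in per_image if math.isfinite(p)]
    skipped = len(per_image) - len(finite)
    mean_p = float(np.mean(finite)) if finite else math.inf
    mean_s = float(np.mean([s for _, _, s in per_image]))
    return MetricReport(
        per_image=per_image,
        mean_psnr_db=mean_p,
        mean_ssim=mean_s,
        scale=scale,
        n_images=len(per_image),
        skipped_psnr_sentinels=skipped,
        conventions=conventions,
    )


def evaluate(
    sr,
    test_images: dict,
    scale: int,
    y_convention: str = "bt601-studio",
    border_crop: int | None = None,
) -> MetricReport:
    """Degrade each held-out HR image, super-resolve, score on Y.

    `sr` is an :class:`HFFEN` or a callable (lr_u8, image_id) -> sr_u8.
    Whole images are evaluated (not patches); a border of `border_crop`
    (default: scale) pixels is excluded on each side.
    """
    if not test_images:
        raise ValueError("empty test set")
    crop = scale if border_crop is None else border_crop
    fn = (lambda lr, _id: sr(lr)) if isinstance(sr, HFFEN) else sr
    rows = []
    for img_id in sorted(test_images):
        hr = np.asarray(test_images[img_id])
        hr = hr[: hr.shape[0] - hr.shape[0] % scale, : hr.shape[1] - hr.shape[1] % scale]
        lr = bicubic_downsample(hr, scale)
        out = np.asarray(fn(lr, img_id))
        if out.shape != hr.shape:
            raise ValueError(
                f"SR output {out.shape} does not match HR {hr.shape} for {img_id}"
            )
        ya = rgb_to_y(out, y_convention)[crop:-crop or None, crop:-crop or None]
        yb = rgb_to_y(hr, y_convention)[crop:-crop or None, crop:-crop or None]
        rows.append((img_id, psnr(ya, yb), ssim(ya, yb)))
    return aggregate(
        rows,
        scale,
        {"y": y_convention, "border_crop": crop, "psnr_peak": 255, "ssim_window": SSIM_WIN},
    )


# ---------------------------------------------------------------------------
# analytic complexity
# ---------------------------------------------------------------------------

class UncountedLayerError(TypeError):
    """The complexity counter met a layer type it has no formula for."""


@dataclass
class ComplexityReport:
    parameters: int
    flops_madds: float
    input_size: tuple

    def to_json(self) -> str:
        return json.dumps(
            {
                "parameters": self.parameters,
                "flops_madds": self.flops_madds,
                "flops_g": self.flops_madds / 1e9,
                "input_size": list(self.input_size),
            },
            indent=1,
        )


def _msa_flops(m: MultiHeadSelfAttention, h: int, w: int) -> float:
    C = m.cfg.channels
    win = m.cfg.spatial_window
    if win == "full" or (h <= int(win) and w <= int(win)):
        n_windows, T = 1, h * w
    else:
        win = int(win)
        n_windows = math.ceil(h / win) * math.ceil(w / win)
        T = win * win
    qkv = T * 3 * C * C
    proj = T * C * C
    attn = 2 * T * T * C  # QK^T scores + weighted sum of V
    return n_windows * (qkv + proj + attn)


def _flops(mod, h: int, w: int) -> tuple[float, int, int]:
    """Multiply-adds of one module at input size (h, w); returns new size."""
    if isinstance(mod, nn.Conv2d):
        return mod.ksize**2 * mod.in_ch * mod.out_ch * h * w, h, w
    if isinstance(mod, nn.Linear):
        return mod.din * mod.dout, h, w  # one token; callers scale
    if isinstance(mod, nn.LayerNorm):
        return 0.0, h, w
    if isinstance(mod, MultiHeadSelfAttention):
        return _msa_flops(mod, h, w), h, w
    if isinstance(mod, ChannelAttention):
        hidden = mod.fc1.dout
        C = mod.cfg.channels
        return C * hidden + hidden * C, h, w
    if isinstance(mod, HybridAttention):
        total = 0.0
        for child in (mod.msa, mod.ca, mod.norm, mod.mlp_in, mod.mlp_out):
            f, h, w = _flops(child, h, w)
            total += f
        return total, h, w
    if isinstance(mod, ResidualBlock):
        f1, _, _ = _flops(mod.conv1, h, w)
        f2, _, _ = _flops(mod.conv2, h, w)
        return f1 + f2, h, w
    if isinstance(mod, ResidualStack):
        return sum(_flops(b, h, w)[0] for b in mod.blocks), h, w
    if isinstance(mod, EDSRBranch):
        return _flops(mod.stack, h, w)
    if isinstance(mod, HFFEBranch):
        total = 0.0
        if mod.use_hiem:
            total += 9 * mod.channels * h * w  # fixed depthwise Laplacian
            total += _flops(mod.refine, h, w)[0]
        if mod.use_ha:
            total += _flops(mod.ha, h, w)[0]
        return total, h, w
    if isinstance(mod, HFFESRModule):
        total = _flops(mod.sr_branch, h, w)[0]
        if mod.hf_branch is not None:
            total += _flops(mod.hf_branch, h, w)[0]
        return total, h, w
    if isinstance(mod, Upsampler):
        total = 0.0
        for conv, r in zip(mod.stages, mod.factors):
            f, _, _ = _flops(conv, h, w)
            total += f
            h, w = h * r, w * r
        f, _, _ = _flops(mod.out_conv, h, w)
        return total + f, h, w
    if isinstance(mod, HFFEN):
        total, h, w = _flops(mod.shallow, h, w)
        for m in mod.modules_:
            f, h, w = _flops(m, h, w)
            total += f
        f, h, w = _flops(mod.agg, h, w)
        total += f
        f, h, w = _flops(mod.upsampler, h, w)
        return total + f, h, w
    raise UncountedLayerError(
        f"no multiply-add formula for layer type {type(mod).__name__}; "
        "refusing to count silently"
    )


def count_complexity(net, input_size: tuple = (192, 192)) -> ComplexityReport:
    """Exact parameter count and analytic multiply-adds for one forward pass.

    `net` may be a single module or a sequence of modules applied in order
    (sizes propagate through upsampling stages).
    """
    mods = list(net) if isinstance(net, (list, tuple)) else [net]
    h, w = input_size
    total = 0.0
    params = 0
    for m in mods:
        f, h, w = _flops(m, h, w)
        total += f
        params += m.n_parameters() if isinstance(m, nn.Module) else 0
    return ComplexityReport(parameters=params, flops_madds=total, input_size=tuple(input_size))
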