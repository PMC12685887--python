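"""Procedural generator of plant-like HR images.

Emulates the high-frequency structures that matter for plant-image
super-resolution — thin branching venation, lesion blobs with sharp 1-px
rims, serrated leaf silhouettes — on a smooth soil-toned background with
mild Gaussian pixel noise. It makes training, evaluation and the ablation
experiment runnable with zero downloads; it is *not* photorealistic and
models no species-specific morphology.

Every image is a pure function of its :class:`SceneSpec` (identical spec ->
bit-identical bytes).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import zoom
from skimage.draw import ellipse, ellipse_perimeter, line

from .blocks import LAPLACIAN_KERNELS

MIN_SIZE = 64


@dataclass
class SceneSpec:
    """Parameters of one synthetic leaf scene.

    venation_density in [0, 1] scales the number of primary side veins;
    serration_amplitude is in pixels; background_noise_sd is in 8-bit
    intensity units. Setting venation_density = lesion_count =
    serration_amplitude = 0 yields a smooth low-frequency image.
    """

    size: int = 96
    seed: int = 0
    venation_density: float = 0.5
    lesion_count: int = 3
    serration_amplitude: float = 3.0
    background_noise_sd: float = 1.0

    def __post_init__(self):
        if self.size < MIN_SIZE:
            raise ValueError(
                f"size must be >= {MIN_SIZE} (structures degenerate), got {self.size}"
            )
        if not 0.0 <= self.venation_density <= 1.0:
            raise ValueError("venation_density must lie in [0, 1]")
        if self.lesion_count < 0 or self.serration_amplitude < 0 or self.background_noise_sd < 0:
            raise ValueError("lesion_count, serration_amplitude, noise sd must be >= 0")


def _smooth_field(rng, size, lo, hi, grid=5):
    coarse = rng.uniform(lo, hi, size=(grid, grid))
    return zoom(coarse, size / grid, order=3)[:size, :size]


def _draw_polyline(mask, pts):
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        rr, cc = line(int(r0), int(c0), int(r1), int(c1))
        ok = (rr >= 0) & (rr < mask.shape[0]) & (cc >= 0) & (cc < mask.shape[1])
        mask[rr[ok], cc[ok]] = True


def _vein(mask, rng, p0, ang, length, depth, density):
    """Recursive binary branching polyline (depth-limited)."""
    if depth == 0 or length < 3:
        return
    mid = p0 + 0.5 * length * np.array([np.sin(ang), np.cos(ang)])
    mid += rng.normal(0, 0.06 * length, 2)
    p1 = p0 + length * np.array([np.sin(ang), np.cos(ang)])
    _draw_polyline(mask, [p0, mid, p1])
    for frac, side in ((0.45, 1.0), (0.8, -1.0)):
        if rng.random() < 0.25 + 0.6 * density:
            child = p0 + frac * (p1 - p0)
            _vein(
                mask, rng, child,
                ang + side * np.deg2rad(30 + rng.normal(0, 8)),
                length * 0.6, depth - 1, density,
            )


def render_scene(spec: SceneSpec):
    """Render one scene; returns (image_u8, masks) where masks holds boolean
    'leaf', 'venation' and 'lesion' layers."""
    rng = np.random.default_rng(spec.seed)
    S = spec.size
    img = np.stack(
        [
            _smooth_field(rng, S, 80, 120),
            _smooth_field(rng, S, 70, 105),
            _smooth_field(rng, S, 55, 90),
        ],
        axis=-1,
    )

    # --- leaf silhouette with sinusoidal serration -------------------------
    cy, cx = S / 2 + rng.normal(0, S * 0.03, 2)
    phi = rng.uniform(0, np.pi)
    R0 = S * rng.uniform(0.30, 0.38)
    aspect = rng.uniform(0.6, 0.85)
    k_serr = int(rng.integers(18, 30))
    psi = rng.uniform(0, 2 * np.pi)
    w_amp = rng.uniform(0.03, 0.08)
    w_phase = rng.uniform(0, 2 * np.pi)

    yy, xx = np.mgrid[0:S, 0:S]
    dy, dx = yy - cy, xx - cx
    rho = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    r_bound = (
        R0 * (1 - (1 - aspect) * np.sin(theta - phi) ** 2)
        + R0 * w_amp * np.sin(2 * (theta - w_phase))
        + spec.serration_amplitude * np.sin(k_serr * theta + psi)
    )
    leaf = rho <= r_bound
    # Boundary sharpness scales with the serration amplitude: a serrated rim
    # is a hard high-frequency edge, a serration-free silhouette blends
    # smoothly into the background (keeps the structure-free scene low-pass).
    edge_w = 3.0 / (1.0 + spec.serration_amplitude)
    alpha = 1.0 / (1.0 + np.exp(-(r_bound - rho) / edge_w))

    hue = rng.normal(0, 10, 3)
    base = np.array([60.0 + hue[0], 128.0 + hue[1] * 1.5, 55.0 + hue[2]])
    shade = _smooth_field(rng, S, -12, 12)
    leaf_img = base[None, None, :] + shade[..., None] - 18.0 * (rho / max(R0, 1))[..., None]
    img = alpha[..., None] * leaf_img + (1 - alpha[..., None]) * img

    # --- venation -----------------------------------------------------------
    veins = np.zeros((S, S), dtype=bool)
    if spec.venation_density > 0:
        d = np.array([np.sin(phi), np.cos(phi)])
        base_pt = np.array([cy, cx]) - 0.85 * R0 * aspect * d
        tip_pt = np.array([cy, cx]) + 0.9 * R0 * aspect * d
        _draw_polyline(veins, [base_pt, (base_pt + tip_pt) / 2, tip_pt])
        n_side = int(round(spec.venation_density * 14))
        for i in range(n_side):
            frac = (i + 1) / (n_side + 1)
            p = base_pt + frac * (tip_pt - base_pt)
            side = 1.0 if i % 2 == 0 else -1.0
            _vein(
                mask=veins, rng=rng, p0=p,
                ang=phi + side * np.deg2rad(42 + rng.normal(0, 6)),
                length=R0 * (0.8 - 0.35 * abs(frac - 0.5) * 2),
                depth=5, density=spec.venation_density,
            )
        # thicken the midrib to ~2 px
        mid2 = np.zeros_like(veins)
        _draw_polyline(mid2, [base_pt + [1, 0], tip_pt + [1, 0]])
        veins |= mid2
        veins &= leaf
        img[veins] *= 0.55

    # --- lesions with sharp 1-px rims ---------------------------------------
    lesions = np.zeros((S, S), dtype=bool)
    inner = leaf & (rho <= 0.7 * r_bound)
    cand = np.argwhere(inner)
    for _ in range(spec.lesion_count):
        if len(cand) == 0:
            break
        ly, lx = cand[int(rng.integers(len(cand)))]
        ra, rb = rng.uniform(2.5, 6.5, 2)
        rot = rng.uniform(0, np.pi)
        rr, cc = ellipse(ly, lx, ra, rb, shape=(S, S), rotation=rot)
        fill = np.zeros((S, S), dtype=bool)
        fill[rr, cc] = True
        rr, cc = ellipse_perimeter(
            int(ly), int(lx), int(round(ra)), int(round(rb)),
            orientation=rot, shape=(S, S),
        )
        rim = np.zeros((S, S), dtype=bool)
        rim[rr, cc] = True
        brown = np.array([128.0, 92.0, 52.0]) + rng.normal(0, 6, 3)
        img = np.where((fill & leaf)[..., None], brown[None, None, :] + shade[..., None], img)
        img = np.where((rim & leaf)[..., None], 0.45 * img, img)
        lesions |= (fill | rim) & leaf

    if spec.background_noise_sd > 0:
        img = img + rng.normal(0, spec.background_noise_sd, img.shape)
    img_u8 = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img_u8, {"leaf": leaf, "venation": veins, "lesion": lesions}


def generate_leaf(spec: SceneSpec) -> np.ndarray:
    """Deterministic RGB leaf image for one scene spec."""
    return render_scene(spec)[0]


def laplacian_energy(img: np.ndarray) -> float:
    """Mean squared 4-neighbour Laplacian response over interior gray pixels."""
    gray = np.asarray(img, dtype=np.float64).mean(axis=-1) if img.ndim == 3 else img.astype(np.float64)
    k = LAPLACIAN_KERNELS["lap4"]
    from scipy.signal import convolve2d

    resp = convolve2d(gray, k, mode="valid")
    return float((resp**2).mean())


def dataset_in_memory(n: int, base_seed: int, template: SceneSpec | None = None) -> dict:
    """n scenes keyed 'leaf_0000'..., per-image seeds base_seed + i."""
    if n < 5:
        raise ValueError("need n >= 5 for a meaningful 80/20 split")
    template = template or SceneSpec()
    out = {}
    for i in range(n):
        d = asdict(template)
        d["seed"] = base_seed + i
        out[f"leaf_{i:04d}"] = generate_leaf(SceneSpec(**d))
    return out


def generate_dataset(
    n: int,
    base_seed: int,
    spec_template: SceneSpec | None = None,
    out_dir: str | Path = "synthetic_leaves",
    overwrite: bool = False,
) -> Path:
    """Write n PNG images plus a JSON-lines manifest of their scene specs."""
    from PIL import Image

    if n < 5:
        raise ValueError("need n >= 5 for a meaningful 80/20 split")
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} exists and is not empty (pass overwrite=True)")
    out.mkdir(parents=True, exist_ok=True)
    template = spec_template or SceneSpec()
    with open(out / "manifest.jsonl", "w") as fh:
        for i in range(n):
            d = asdict(template)
            d["seed"] = base_seed + i
            spec = SceneSpec(**d)
            name = f"leaf_{i:04d}.png"
            Image.fromarray(generate_leaf(spec)).save(out / name)
            fh.write(json.dumps({"id": name[:-4], "file": name, **d}) + "\n")
    return out
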