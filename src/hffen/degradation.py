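"""Data protocol: seeded 80/20 split, random HR patch extraction, dihedral
augmentation, and bicubic LR synthesis at x2/x3/x4.

LR images are always computed *from* HR patches, never the reverse, and
training patches are drawn strictly from the training split; an audit
operation verifies the absence of test leakage from recorded provenance.

The bicubic resampler is implemented as a separable Catmull-Rom (a = -0.5)
kernel with antialiasing when downscaling — the convention of standard SR
benchmark data preparation — computed in float64 as two matrix products per
channel. Because the same symmetric weight matrix acts on rows and columns,
resampling commutes with 90-degree rotations, which the tests use as a
symmetry cross-check.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

DEFAULT_PATCH = 192
TRAIN_FRACTION = 0.8


class LeakageError(AssertionError):
    """A training patch originated from a held-out test image."""


class UndersizedImageError(ValueError):
    """Image smaller than the requested patch size; callers skip and count."""


# ---------------------------------------------------------------------------
# dataset split
# ---------------------------------------------------------------------------

@dataclass
class SplitManifest:
    """A reproducible 80/20 partition of image ids."""

    train_ids: list
    test_ids: list
    seed: int
    fractions: tuple = (TRAIN_FRACTION, 1.0 - TRAIN_FRACTION)

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "fractions": list(self.fractions),
                "train_ids": list(self.train_ids),
                "test_ids": list(self.test_ids),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "SplitManifest":
        d = json.loads(text)
        return cls(
            train_ids=d["train_ids"],
            test_ids=d["test_ids"],
            seed=d["seed"],
            fractions=tuple(d["fractions"]),
        )


def split_dataset(ids, seed: int) -> SplitManifest:
    """Seeded shuffle, floor(0.8 n) train ids, remainder test.

    Refuses fewer than 5 ids (the 20% slice would be empty).
    """
    ids = list(ids)
    if len(ids) < 5:
        raise ValueError(f"need at least 5 ids to split 80/20, got {len(ids)}")
    order = np.random.default_rng(seed).permutation(len(ids))
    n_train = int(np.floor(TRAIN_FRACTION * len(ids)))
    train = [ids[i] for i in order[:n_train]]
    test = [ids[i] for i in order[n_train:]]
    return SplitManifest(train_ids=train, test_ids=test, seed=seed)


# ---------------------------------------------------------------------------
# patches and augmentation
# ---------------------------------------------------------------------------

def extract_patch(hr_image: np.ndarray, size: int, rng: np.random.Generator):
    """Uniformly positioned size x size crop; returns (patch, (top, left))."""
    H, W = hr_image.shape[:2]
    if H < size or W < size:
        raise UndersizedImageError(
            f"image {H}x{W} smaller than patch size {size}"
        )
    top = int(rng.integers(0, H - size + 1))
    left = int(rng.integers(0, W - size + 1))
    return hr_image[top : top + size, left : left + size].copy(), (top, left)


def augment(patch: np.ndarray, op_id: int) -> np.ndarray:
    """Apply the op_id-th element of the dihedral group of order 8.

    0..3 are rotations by 0/90/180/270 degrees; 4..7 are the same rotations
    after a horizontal flip. Requires a square patch.
    """
    if not (0 <= int(op_id) <= 7):
        raise ValueError(f"dihedral op_id must be in 0..7, got {op_id}")
    if patch.shape[0] != patch.shape[1]:
        raise ValueError("dihedral augmentation requires a square patch")
    out = patch[:, ::-1] if op_id >= 4 else patch
    return np.ascontiguousarray(np.rot90(out, k=op_id % 4))


# ---------------------------------------------------------------------------
# bicubic resampling
# ---------------------------------------------------------------------------

def _cubic(x: np.ndarray, a: float = -0.5) -> np.ndarray:
    x = np.abs(x)
    return np.where(
        x <= 1,
        (a + 2) * x**3 - (a + 3) * x**2 + 1,
        np.where(x < 2, a * x**3 - 5 * a * x**2 + 8 * a * x - 4 * a, 0.0),
    )


@lru_cache(maxsize=64)
def _resample_matrix(n_in: int, n_out: int) -> np.ndarray:
    """(n_out, n_in) row-normalised bicubic weights; kernel widened by the
    scale factor when downscaling (antialias). Edges replicate."""
    scale = n_in / n_out
    width = max(scale, 1.0)
    centers = (np.arange(n_out) + 0.5) * scale - 0.5
    reach = int(np.ceil(2 * width)) + 1
    base = np.floor(centers).astype(int)
    offsets = np.arange(-reach, reach + 1)
    idx = base[:, None] + offsets[None, :]
    w = _cubic((centers[:, None] - idx) / width) / width
    idx = np.clip(idx, 0, n_in - 1)
    W = np.zeros((n_out, n_in))
    np.add.at(W, (np.repeat(np.arange(n_out), idx.shape[1]), idx.ravel()), w.ravel())
    W /= W.sum(axis=1, keepdims=True)
    return W


def _resample(img: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Separable bicubic resample of an (H, W[, C]) array, float64, unclipped."""
    x = img.astype(np.float64)
    Wr = _resample_matrix(x.shape[0], out_h)
    Wc = _resample_matrix(x.shape[1], out_w)
    if x.ndim == 2:
        return Wr @ x @ Wc.T
    return np.einsum("hi,iwc,wj->hjc", Wr, x, Wc.T, optimize=True)


def _to_u8(x: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(x), 0, 255).astype(np.uint8)


def bicubic_downsample(hr: np.ndarray, scale: int) -> np.ndarray:
    """Antialiased bicubic reduction by an integer factor.

    Dimensions not divisible by `scale` are cropped to the largest divisible
    size first.
    """
    H, W = hr.shape[:2]
    Hc, Wc = H - H % scale, W - W % scale
    hr = hr[:Hc, :Wc]
    return _to_u8(_resample(hr, Hc // scale, Wc // scale))


def bicubic_upsample(lr: np.ndarray, scale: int) -> np.ndarray:
    """Plain bicubic enlargement (the classical SR baseline)."""
    H, W = lr.shape[:2]
    return _to_u8(_resample(lr, H * scale, W * scale))


# ---------------------------------------------------------------------------
# patch pairs and the training stream
# ---------------------------------------------------------------------------

@dataclass
class PatchPair:
    """An aligned (LR, HR) pair; hr is exactly scale x the lr size and lr was
    derived from hr by bicubic downsampling."""

    hr: np.ndarray
    lr: np.ndarray
    scale: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        sh, sw = self.hr.shape[:2]
        lh, lw = self.lr.shape[:2]
        if (sh, sw) != (self.scale * lh, self.scale * lw):
            raise ValueError(
                f"HR {sh}x{sw} is not {self.scale}x the LR size {lh}x{lw}"
            )


def make_pair(hr_patch: np.ndarray, scale: int, provenance: dict | None = None) -> PatchPair:
    return PatchPair(
        hr=hr_patch,
        lr=bicubic_downsample(hr_patch, scale),
        scale=scale,
        provenance=provenance or {},
    )


class PatchStream:
    """Deterministic, resumable stream of augmented training batches.

    The batch at iteration t is drawn with a generator seeded by (seed, t),
    so any iteration's batch is reproducible without replaying the stream —
    this is what makes training checkpoints exactly resumable.
    """

    def __init__(
        self,
        images: dict,
        manifest: SplitManifest,
        scale: int,
        patch_size: int = DEFAULT_PATCH,
        batch_size: int = 16,
        seed: int = 0,
        augment_patches: bool = True,
    ):
        if patch_size % scale != 0:
            raise ValueError("patch size must be divisible by the scale factor")
        self.scale = scale
        self.patch_size = patch_size
        self.batch_size = batch_size
        self.seed = seed
        self.augment_patches = augment_patches
        self.manifest = manifest
        self.skipped: list = []
        self.ids = []
        for i in manifest.train_ids:
            img = images[i]
            if img.shape[0] < patch_size or img.shape[1] < patch_size:
                self.skipped.append(i)
            else:
                self.ids.append(i)
        if not self.ids:
            raise ValueError("no training image is large enough for the patch size")
        self.images = images

    def batch(self, t: int) -> list[PatchPair]:
        rng = np.random.default_rng([self.seed, int(t)])
        pairs = []
        for _ in range(self.batch_size):
            img_id = self.ids[int(rng.integers(len(self.ids)))]
            patch, offset = extract_patch(self.images[img_id], self.patch_size, rng)
            op = int(rng.integers(8)) if self.augment_patches else 0
            patch = augment(patch, op)
            pairs.append(
                make_pair(
                    patch,
                    self.scale,
                    {"source_id": img_id, "offset": offset, "aug_id": op},
                )
            )
        return pairs


def audit_no_leakage(provenances, manifest: SplitManifest):
    """Assert that every recorded patch came from the training split."""
    test = set(manifest.test_ids)
    train = set(manifest.train_ids)
    for p in provenances:
        sid = p["source_id"]
        if sid in test or sid not in train:
            raise LeakageError(f"patch drawn from non-training image {sid!r}")
    return len(list(provenances)) if not hasattr(provenances, "__len__") else len(provenances)
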