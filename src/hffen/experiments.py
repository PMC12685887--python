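"""Desk-scale reference experiments.

The ablation-direction experiment reproduces, at CPU scale, the qualitative
ordering of the published ablation: on a 200-image synthetic leaf dataset
(80/20 split), the trained baseline and the trained full HF-FE variant should
both beat plain bicubic interpolation on mean Y-channel PSNR, and the full
variant should not fall below the baseline, averaged over independent seeds.

Problem sizes (image count, split, model width, iteration count) are the
package's desk profile; docs/methods.md discusses how they were chosen.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .degradation import PatchStream, bicubic_upsample, split_dataset
from .metrics import count_complexity, evaluate
from .network import HFFEN
from .synthetic_plants import SceneSpec, dataset_in_memory
from .training import Adam, profile, train

N_IMAGES = 200
IMAGE_SIZE = 96
N_SEEDS = 3
SCALE = 2


def ablation_direction(
    seed: int,
    n_images: int = N_IMAGES,
    n_seeds: int = N_SEEDS,
    total_iters: int | None = None,
) -> dict:
    """Train baseline and +HIEM+HA under identical schedules, several seeds.

    Returns per-seed and seed-averaged mean Y-PSNR/SSIM for bicubic, the
    HF-FE-disabled baseline and the full network, plus analytic complexity.
    All randomness derives from `seed`.
    """
    images = dataset_in_memory(
        n_images, base_seed=seed * 1000, template=SceneSpec(size=IMAGE_SIZE)
    )
    manifest = split_dataset(sorted(images), seed=seed)
    train_imgs = {i: images[i] for i in manifest.train_ids}
    test_imgs = {i: images[i] for i in manifest.test_ids}

    net_cfg, tr_cfg = profile("desk", scale=SCALE, seed=seed)
    if total_iters is not None:
        tr_cfg = dataclasses.replace(tr_cfg, total_iters=total_iters)

    bic = evaluate(lambda lr, _id: bicubic_upsample(lr, SCALE), test_imgs, SCALE)
    out = {
        "bicubic": {"psnr_db": bic.mean_psnr_db, "ssim": bic.mean_ssim},
        "variants": {},
        "n_images": n_images,
        "n_test": len(test_imgs),
        "total_iters": tr_cfg.total_iters,
    }
    variants = {
        "baseline": {"use_hiem": False, "use_ha": False},
        "full": {"use_hiem": True, "use_ha": True},
    }
    for name, kw in variants.items():
        cfg = dataclasses.replace(net_cfg, **kw)
        comp = count_complexity(HFFEN(cfg, seed=0), (192, 192))
        runs = []
        for k in range(n_seeds):
            run_seed = seed + 17 * (k + 1)
            stream = PatchStream(
                train_imgs, manifest, scale=SCALE,
                patch_size=tr_cfg.patch_size, batch_size=tr_cfg.batch_size,
                seed=run_seed,
            )
            net = HFFEN(cfg, seed=run_seed)
            cfg_k = dataclasses.replace(tr_cfg, seed=run_seed)
            res = train(net, stream, cfg_k, opt=Adam(net.parameters(), betas=cfg_k.betas, eps=cfg_k.eps))
            rep = evaluate(net, test_imgs, SCALE)
            runs.append(
                {"seed": run_seed, "psnr_db": rep.mean_psnr_db, "ssim": rep.mean_ssim,
                 "final_loss": res.loss_trace[-1][2]}
            )
        out["variants"][name] = {
            "runs": runs,
            "mean_psnr_db": float(np.mean([r["psnr_db"] for r in runs])),
            "mean_ssim": float(np.mean([r["ssim"] for r in runs])),
            "parameters": comp.parameters,
            "flops_madds_192": comp.flops_madds,
        }
    return out


def flops_overhead(input_size: int = 192) -> dict:
    """Analytic multiply-add overhead of the full HF-FE branch on the
    paper-profile reference network."""
    net_cfg, _ = profile("paper")
    full = count_complexity(HFFEN(net_cfg, seed=0), (input_size, input_size))
    base_cfg = dataclasses.replace(net_cfg, use_hiem=False, use_ha=False)
    base = count_complexity(HFFEN(base_cfg, seed=0), (input_size, input_size))
    return {
        "baseline_flops_madds": base.flops_madds,
        "full_flops_madds": full.flops_madds,
        "flops_overhead_percent": 100.0 * (full.flops_madds - base.flops_madds) / base.flops_madds,
        "baseline_parameters": base.parameters,
        "full_parameters": full.parameters,
        "parameter_overhead_percent": 100.0 * (full.parameters - base.parameters) / base.parameters,
        "input_size": input_size,
    }
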