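"""Optimisation protocol: L1 loss, Adam, step-halving LR schedule, global
gradient-norm clipping, seeded and exactly resumable iteration loop.

One "iteration" is one optimisation step on one randomly sampled batch of
patch pairs. Separate models are trained per scale factor; a stream emitting
a pair of the wrong scale aborts the run. The learning rate follows the
closed form lr(t) = lr0 * 0.5^floor(t / halve_every).

Two profiles are provided: ``paper`` mirrors the published protocol
(400k iterations, 192-px patches, 1e-4 initial LR halved every 100k, the
full-width reference network), and ``desk`` is the CPU-scale profile used by
the tests and the acceptance experiment (tiny network, short schedule; see
docs/methods.md for the reasoning behind its sizes).
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .attention import AttentionConfig
from .autograd import Tensor
from .blocks import HiemConfig
from .degradation import PatchPair
from .network import HFFEN, NetworkConfig


@dataclass
class TrainConfig:
    lr0: float = 1e-4
    betas: tuple = (0.9, 0.999)
    halve_every: int = 100_000
    clip_norm: float = 5.0
    total_iters: int = 400_000
    batch_size: int = 16
    patch_size: int = 192
    seed: int = 0
    scale: int = 2
    eps: float = 1e-8
    log_every: int = 50
    checkpoint_every: int = 1000

    def to_dict(self) -> dict:
        return asdict(self)


def profile(name: str, scale: int = 2, seed: int = 0) -> tuple[NetworkConfig, TrainConfig]:
    """Named (network, training) configuration bundles."""
    if name == "paper":
        net = NetworkConfig(channels=64, n_modules=4, scale=scale, backbone_blocks=16)
        tr = TrainConfig(scale=scale, seed=seed)
    elif name == "desk":
        net = NetworkConfig(
            channels=24,
            n_modules=1,
            scale=scale,
            backbone_blocks=2,
            hiem=HiemConfig(depth=1, bottleneck=4),
            ha=AttentionConfig(channels=24, heads=2, ca_reduction=8),
        )
        tr = TrainConfig(
            lr0=2e-3,
            halve_every=1500,
            total_iters=4500,
            batch_size=2,
            patch_size=48,
            scale=scale,
            seed=seed,
            checkpoint_every=500,
        )
    else:
        raise ValueError(f"unknown profile {name!r}; choose paper|desk")
    return net, tr


# ---------------------------------------------------------------------------
# loss / schedule / clipping
# ---------------------------------------------------------------------------

def l1_loss(pred: Tensor, target: Tensor) -> Tensor:
    """Mean absolute difference over all pixels and channels (normalised units)."""
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    return (pred - target).abs().mean()


def lr_at(t: int, cfg: TrainConfig) -> float:
    """lr0 * 0.5^floor(t / halve_every)."""
    if t < 0:
        raise ValueError("iteration index must be >= 0")
    return cfg.lr0 * 0.5 ** (t // cfg.halve_every)


def clip_gradients(params, max_norm: float) -> float:
    """Scale all gradients so the global L2 norm is at most `max_norm`.

    Returns the pre-clip norm; direction is preserved when scaling occurs.
    Aborts on non-finite gradients.
    """
    sq = 0.0
    grads = []
    for p in params:
        if p.grad is None:
            continue
        if not np.isfinite(p.grad).all():
            raise FloatingPointError("non-finite gradient; aborting iteration")
        sq += float((p.grad.astype(np.float64) ** 2).sum())
        grads.append(p)
    norm = float(np.sqrt(sq))
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for p in grads:
            p.grad *= scale
    return norm


def global_grad_norm(params) -> float:
    return float(
        np.sqrt(
            sum(
                float((p.grad.astype(np.float64) ** 2).sum())
                for p in params
                if p.grad is not None
            )
        )
    )


class Adam:
    """Adam with bias correction; state is serialisable for exact resume."""

    def __init__(self, params, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float):
        self.t += 1
        b1, b2 = self.b1, self.b2
        c1 = 1 - b1**self.t
        c2 = 1 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= lr * (m / c1) / (np.sqrt(v / c2) + self.eps)

    def state(self) -> dict:
        return {"t": self.t, "m": [m.copy() for m in self.m], "v": [v.copy() for v in self.v]}

    def load_state(self, state: dict):
        self.t = int(state["t"])
        self.m = [np.asarray(m).copy() for m in state["m"]]
        self.v = [np.asarray(v).copy() for v in state["v"]]


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(
    path: str | Path,
    net: HFFEN,
    train_cfg: TrainConfig,
    opt: Adam | None = None,
    iteration: int = 0,
    seed: int | None = None,
):
    """Single-file archive: weights + full configs + iteration + Adam state."""
    payload = {
        "meta": np.frombuffer(
            json.dumps(
                {
                    "network": net.cfg.to_dict(),
                    "train": train_cfg.to_dict(),
                    "iteration": iteration,
                    "seed": train_cfg.seed if seed is None else seed,
                }
            ).encode(),
            dtype=np.uint8,
        )
    }
    for name, p in net.named_parameters():
        payload[f"w/{name}"] = p.data
    if opt is not None:
        payload["opt/t"] = np.array(opt.t)
        for i, (m, v) in enumerate(zip(opt.m, opt.v)):
            payload[f"opt/m{i}"] = m
            payload[f"opt/v{i}"] = v
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wb") as fh:
        np.savez(fh, **payload)


def load_checkpoint(path: str | Path):
    """Returns (net, train_cfg, iteration, opt_state-or-None)."""
    with np.load(Path(path), allow_pickle=False) as z:
        if "meta" not in z:
            raise ValueError("corrupt checkpoint: missing field 'meta'")
        meta = json.loads(bytes(z["meta"]).decode())
        for key in ("network", "train", "iteration"):
            if key not in meta:
                raise ValueError(f"corrupt checkpoint: missing field {key!r}")
        net_cfg = NetworkConfig.from_dict(meta["network"])
        train_cfg = TrainConfig(**meta["train"])
        net = HFFEN(net_cfg, seed=meta.get("seed", 0))
        net.load_state_dict(
            {k[2:]: z[k] for k in z.files if k.startswith("w/")}
        )
        opt_state = None
        if "opt/t" in z.files:
            n = sum(1 for k in z.files if k.startswith("opt/m"))
            opt_state = {
                "t": int(z["opt/t"]),
                "m": [z[f"opt/m{i}"] for i in range(n)],
                "v": [z[f"opt/v{i}"] for i in range(n)],
            }
    return net, train_cfg, int(meta["iteration"]), opt_state


# ---------------------------------------------------------------------------
# the training loop
# ---------------------------------------------------------------------------

def _pairs_to_arrays(pairs: list[PatchPair], scale: int):
    for p in pairs:
        if p.scale != scale:
            raise ValueError(
                f"stream emitted a x{p.scale} pair into a x{scale} run; aborting"
            )
    lr = np.stack([p.lr for p in pairs]).astype(np.float32) / 255.0
    hr = np.stack([p.hr for p in pairs]).astype(np.float32) / 255.0
    return (
        Tensor(np.ascontiguousarray(lr.transpose(0, 3, 1, 2))),
        Tensor(np.ascontiguousarray(hr.transpose(0, 3, 1, 2))),
        [p.provenance for p in pairs],
    )


@dataclass
class TrainResult:
    loss_trace: list  # (iteration, lr, loss)
    final_iteration: int
    checkpoint: Path | None
    provenance_log: list = field(default_factory=list)
    aborted: str | None = None

    def trace_csv(self) -> str:
        buf = io.StringIO()
        buf.write("iteration,lr,loss\n")
        for t, lr, loss in self.loss_trace:
            buf.write(f"{t},{lr:.8g},{loss:.8g}\n")
        return buf.getvalue()


def train(
    net: HFFEN,
    stream,
    cfg: TrainConfig,
    out_dir: str | Path | None = None,
    start_iteration: int = 0,
    opt: Adam | None = None,
    keep_provenance: bool = False,
    stop_after: int | None = None,
) -> TrainResult:
    """Run (total_iters - start_iteration) optimisation steps.

    The batch at iteration t depends only on (stream seed, t), so resuming
    from a checkpoint at iteration k reproduces the un-interrupted run
    bit for bit. On a NaN loss the run aborts and the last-good checkpoint
    is retained.
    """
    if net.cfg.scale != cfg.scale:
        raise ValueError(
            f"network scale x{net.cfg.scale} != training scale x{cfg.scale}"
        )
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    opt = opt or Adam(net.parameters(), betas=cfg.betas, eps=cfg.eps)
    params = opt.params
    trace: list = []
    prov_log: list = []
    ckpt_path = out / f"checkpoint_x{cfg.scale}.npz" if out is not None else None
    stop = cfg.total_iters if stop_after is None else min(stop_after, cfg.total_iters)

    for t in range(start_iteration, stop):
        x, y, prov = _pairs_to_arrays(stream.batch(t), cfg.scale)
        if keep_provenance:
            prov_log.extend(prov)
        pred = net.forward_features(x)
        loss = l1_loss(pred, y)
        loss_val = float(loss.data)
        if not np.isfinite(loss_val):
            return TrainResult(trace, t, ckpt_path, prov_log, aborted=f"NaN loss at iteration {t}")
        net.zero_grad()
        loss.backward()
        clip_gradients(params, cfg.clip_norm)
        post = global_grad_norm(params)
        assert post <= cfg.clip_norm * (1 + 1e-5), "post-clip norm exceeded the bound"
        opt.step(lr_at(t, cfg))
        if t % cfg.log_every == 0 or t == cfg.total_iters - 1:
            trace.append((t, lr_at(t, cfg), loss_val))
        if ckpt_path is not None and (
            (t + 1) % cfg.checkpoint_every == 0 or t == cfg.total_iters - 1
        ):
            save_checkpoint(ckpt_path, net, cfg, opt, iteration=t + 1)

    if out is not None:
        result = TrainResult(trace, cfg.total_iters, ckpt_path, prov_log)
        (out / f"loss_trace_x{cfg.scale}.csv").write_text(result.trace_csv())
        return result
    return TrainResult(trace, cfg.total_iters, ckpt_path, prov_log)


def resume(path: str | Path, stream, out_dir: str | Path | None = None) -> tuple[HFFEN, TrainResult]:
    """Continue a checkpointed run to its configured total_iters."""
    net, cfg, iteration, opt_state = load_checkpoint(path)
    opt = Adam(net.parameters(), betas=cfg.betas, eps=cfg.eps)
    if opt_state is not None:
        opt.load_state(opt_state)
    result = train(net, stream, cfg, out_dir=out_dir, start_iteration=iteration, opt=opt)
    return net, result
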