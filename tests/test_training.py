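"""Optimisation protocol: loss, schedule, clipping, loop determinism."""

import dataclasses

import numpy as np
import pytest

from hffen.autograd import Tensor
from hffen.degradation import PatchStream, split_dataset
from hffen.network import HFFEN
from hffen.synthetic_plants import SceneSpec, generate_leaf
from hffen.training import (
    Adam,
    TrainConfig,
    clip_gradients,
    l1_loss,
    load_checkpoint,
    lr_at,
    profile,
    resume,
    save_checkpoint,
    train,
)

SMOKE_NET = dict(channels=8, n_modules=1, backbone_blocks=1)


@pytest.fixture(scope="module")
def smoke_data():
    images = {f"leaf_{i}": generate_leaf(SceneSpec(size=64, seed=300 + i)) for i in range(8)}
    manifest = split_dataset(sorted(images), seed=2)
    return images, manifest


def smoke_stream(images, manifest, seed=3, batch=2):
    return PatchStream(images, manifest, scale=2, patch_size=32, batch_size=batch, seed=seed)


def smoke_net(seed=0):
    from hffen.attention import AttentionConfig
    from hffen.blocks import HiemConfig
    from hffen.network import NetworkConfig

    cfg = NetworkConfig(
        scale=2, hiem=HiemConfig(depth=1, bottleneck=2),
        ha=AttentionConfig(channels=8, heads=2, ca_reduction=4), **SMOKE_NET,
    )
    return HFFEN(cfg, seed=seed)


class TestL1Loss:
    def test_identical_inputs_give_zero(self, rng):
        x = Tensor(rng.random((1, 3, 8, 8)))
        assert float(l1_loss(x, x).data) == 0.0

    def test_constant_offset(self, rng):
        x = Tensor(rng.random((2, 3, 5, 5)))
        y = Tensor(x.data + 0.1)
        assert float(l1_loss(x, y).data) == pytest.approx(0.1, abs=1e-12)

    def test_matches_brute_force_mean_absolute_difference(self, rng):
        a, b = rng.random((2, 3, 7, 7)), rng.random((2, 3, 7, 7))
        ref = float(np.abs(a - b).mean())
        assert float(l1_loss(Tensor(a), Tensor(b)).data) == pytest.approx(ref, abs=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            l1_loss(Tensor(rng.random((1, 3, 4, 4))), Tensor(rng.random((1, 3, 4, 5))))


class TestLrSchedule:
    def test_closed_form_values(self):
        cfg = TrainConfig()
        assert lr_at(0, cfg) == pytest.approx(1e-4)
        assert lr_at(99_999, cfg) == pytest.approx(1e-4)
        assert lr_at(100_000, cfg) == pytest.approx(5e-5)
        assert lr_at(350_000, cfg) == pytest.approx(1.25e-5)

    def test_matches_closed_form_at_every_logged_step(self):
        cfg = TrainConfig(lr0=2e-3, halve_every=7)
        for t in range(40):
            assert lr_at(t, cfg) == cfg.lr0 * 0.5 ** (t // 7)


class TestClipGradients:
    def _params(self, grads):
        ps = []
        for g in grads:
            p = Tensor(np.zeros_like(g), requires_grad=True)
            p.grad = g.copy()
            ps.append(p)
        return ps

    def test_below_threshold_untouched(self, rng):
        g = rng.normal(size=(5,))
        g *= 2.0 / np.linalg.norm(g)
        ps = self._params([g])
        norm = clip_gradients(ps, 5.0)
        assert norm == pytest.approx(2.0)
        np.testing.assert_array_equal(ps[0].grad, g)

    def test_scaling_preserves_direction_and_hits_bound(self, rng):
        g = rng.normal(size=(10,))
        g *= 50.0 / np.linalg.norm(g)
        ps = self._params([g])
        clip_gradients(ps, 5.0)
        assert np.linalg.norm(ps[0].grad) == pytest.approx(5.0)
        np.testing.assert_allclose(ps[0].grad, g * 0.1, rtol=1e-12)

    def test_zero_gradients_stay_zero(self):
        ps = self._params([np.zeros(4)])
        assert clip_gradients(ps, 5.0) == 0.0
        np.testing.assert_array_equal(ps[0].grad, 0.0)

    def test_non_finite_gradients_abort(self):
        ps = self._params([np.array([1.0, np.nan])])
        with pytest.raises(FloatingPointError):
            clip_gradients(ps, 5.0)


class TestTrainLoop:
    def test_smoke_run_loss_trend_decreases(self, smoke_data):
        images, manifest = smoke_data
        net = smoke_net()
        cfg = TrainConfig(lr0=1e-3, halve_every=1000, total_iters=200,
                          batch_size=2, patch_size=32, scale=2, seed=3, log_every=1)
        res = train(net, smoke_stream(images, manifest), cfg)
        losses = [l for _, _, l in res.loss_trace]
        assert np.mean(losses[-50:]) < np.mean(losses[:50])
        assert res.aborted is None

    def test_two_identical_runs_are_bit_identical(self, smoke_data):
        images, manifest = smoke_data
        cfg = TrainConfig(lr0=1e-3, total_iters=20, batch_size=2,
                          patch_size=32, scale=2, seed=5, log_every=1)
        traces = []
        for _ in range(2):
            net = smoke_net(seed=7)
            res = train(net, smoke_stream(images, manifest, seed=5), cfg)
            traces.append(res.loss_trace)
        assert traces[0] == traces[1]

    def test_resume_reproduces_uninterrupted_run_bit_for_bit(self, smoke_data, tmp_path):
        images, manifest = smoke_data
        cfg = TrainConfig(lr0=1e-3, total_iters=60, batch_size=2, patch_size=32,
                          scale=2, seed=5, log_every=1, checkpoint_every=30)
        straight = smoke_net(seed=1)
        train(straight, smoke_stream(images, manifest, seed=5), cfg)

        interrupted = smoke_net(seed=1)
        train(interrupted, smoke_stream(images, manifest, seed=5), cfg,
              out_dir=tmp_path, stop_after=30)
        resumed, _ = resume(tmp_path / "checkpoint_x2.npz",
                            smoke_stream(images, manifest, seed=5))
        for (n1, p1), (n2, p2) in zip(straight.named_parameters(), resumed.named_parameters()):
            assert n1 == n2
            np.testing.assert_array_equal(p1.data, p2.data)

    def test_wrong_scale_pair_aborts_immediately(self, smoke_data):
        images, manifest = smoke_data

        class WrongScaleStream:
            def batch(self, t):
                return smoke_stream(images, manifest).batch(t)

        net_cfg, _ = profile("desk", scale=3)
        net = HFFEN(net_cfg, seed=0)
        cfg = TrainConfig(total_iters=5, batch_size=2, patch_size=33, scale=3, seed=0)
        with pytest.raises(ValueError, match="x2"):
            train(net, WrongScaleStream(), cfg)

    def test_checkpoint_round_trip_and_corruption_diagnostics(self, smoke_data, tmp_path):
        net = smoke_net(seed=2)
        cfg = TrainConfig(scale=2, seed=9)
        path = tmp_path / "ck.npz"
        save_checkpoint(path, net, cfg, iteration=17)
        net2, cfg2, it, _ = load_checkpoint(path)
        assert it == 17 and cfg2.seed == 9
        for (n1, p1), (n2, p2) in zip(net.named_parameters(), net2.named_parameters()):
            np.testing.assert_array_equal(p1.data, p2.data)
        bad = tmp_path / "bad.npz"
        np.savez(bad, junk=np.zeros(3))
        with pytest.raises(ValueError, match="meta"):
            load_checkpoint(bad)
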