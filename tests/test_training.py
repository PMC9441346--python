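"""Alternating training loop: parameter isolation, determinism, checkpoints."""

import hashlib

import numpy as np
import pytest

from sadgan import nn
from sadgan.discriminator import DiscConfig, Discriminator
from sadgan.generator import GenConfig, Generator
from sadgan.losses import LossConfig, cross_entropy_loss
from sadgan.nn import Tensor
from sadgan.phantom import PhantomSpec, generate_dataset
from sadgan.preprocess import PreprocConfig
from sadgan.training import (TrainConfig, discriminator_half_step, fit,
                             generator_half_step, load_checkpoint, prepare_pair,
                             save_checkpoint, train_step)

GEN_CFG = dict(base_channels=4, seed=0)
DISC_CFG = dict(stages=2, base_channels=8, seed=1)


def _params_hash(module):
    h = hashlib.sha256()
    for _, p in sorted(module.named_parameters()):
        h.update(p.data.tobytes())
    return h.hexdigest()


def _tiny_setup():
    gen = Generator(GenConfig(**GEN_CFG))
    disc = Discriminator(DiscConfig(**DISC_CFG))
    g_opt = nn.Adam(gen.parameters(), lr=2.5e-4, weight_decay=1e-4)
    d_opt = nn.Adam(disc.parameters(), lr=1e-4)
    rng = np.random.default_rng(0)
    image = rng.random((16, 16)).astype(np.float32)
    truth = (rng.random((16, 16)) > 0.7).astype(np.uint8)
    return gen, disc, g_opt, d_opt, image, truth


def _tiny_dataset(n=3):
    spec = PhantomSpec(height=32, width=32, n_trees=2, branch_depth=3,
                       root_width_px=2.0)
    return generate_dataset(spec, n, seed=5)


class TestHalfStepIsolation:
    def test_generator_half_step_leaves_discriminator_untouched(self):
        gen, disc, g_opt, d_opt, image, truth = _tiny_setup()
        before = _params_hash(disc)
        generator_half_step(gen, disc, g_opt, Tensor(image[None, None]), truth,
                            LossConfig(lambda_adv=0.1))
        assert _params_hash(disc) == before
        assert _params_hash(gen) != _params_hash(Generator(GenConfig(**GEN_CFG)))

    def test_discriminator_half_step_leaves_generator_untouched(self):
        gen, disc, g_opt, d_opt, image, truth = _tiny_setup()
        g_before = _params_hash(gen)
        d_before = _params_hash(disc)
        discriminator_half_step(gen, disc, d_opt, Tensor(image[None, None]),
                                truth, LossConfig())
        assert _params_hash(gen) == g_before
        assert _params_hash(disc) != d_before

    def test_one_step_changes_both_networks(self):
        gen, disc, g_opt, d_opt, image, truth = _tiny_setup()
        g0, d0 = _params_hash(gen), _params_hash(disc)
        rec = train_step(gen, disc, g_opt, d_opt, image, truth, LossConfig())
        assert _params_hash(gen) != g0 and _params_hash(disc) != d0
        for key in ("loss_d", "loss_ce", "loss_adv", "loss_seg"):
            assert np.isfinite(rec[key])


class TestAblationIdentity:
    def test_lambda_zero_matches_plain_ce_training_bitwise(self):
        """With lambda_adv = 0 the generator trajectory equals CE-only training."""
        gen_a, disc, g_opt_a, d_opt, image, truth = _tiny_setup()
        cfg = LossConfig(lambda_adv=0.0)
        for it in range(3):
            train_step(gen_a, disc, g_opt_a, d_opt, image, truth, cfg, it)

        gen_b = Generator(GenConfig(**GEN_CFG))
        g_opt_b = nn.Adam(gen_b.parameters(), lr=2.5e-4, weight_decay=1e-4)
        for _ in range(3):
            g_opt_b.zero_grad()
            prob = gen_b(Tensor(image[None, None]))
            cross_entropy_loss(prob, truth, reduction="mean").backward()
            g_opt_b.step()
        for (na, pa), (nb, pb) in zip(sorted(gen_a.named_parameters()),
                                      sorted(gen_b.named_parameters())):
            assert na == nb
            np.testing.assert_array_equal(pa.data, pb.data)


class TestFit:
    def test_zero_iterations_returns_initial_weights(self, tmp_path):
        samples = _tiny_dataset(2)
        cfg = TrainConfig(iterations=0, seed=0)
        gen, disc, log = fit(samples, None, GenConfig(**GEN_CFG),
                             DiscConfig(**DISC_CFG), cfg, out_dir=tmp_path / "run")
        assert log == []
        assert _params_hash(gen) == _params_hash(Generator(GenConfig(**GEN_CFG)))
        assert (tmp_path / "run" / "train_log.jsonl").read_text() == ""

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fit([], None)

    def test_same_seed_gives_identical_loss_log(self):
        samples = _tiny_dataset(3)
        cfg = TrainConfig(iterations=4, seed=7, val_every=100)
        _, _, log1 = fit(samples, None, GenConfig(**GEN_CFG),
                         DiscConfig(**DISC_CFG), cfg)
        _, _, log2 = fit(samples, None, GenConfig(**GEN_CFG),
                         DiscConfig(**DISC_CFG), cfg)
        assert [r["loss_seg"] for r in log1] == [r["loss_seg"] for r in log2]
        assert [r["loss_d"] for r in log1] == [r["loss_d"] for r in log2]

    def test_different_seed_gives_different_log(self):
        samples = _tiny_dataset(3)
        logs = []
        for seed in (0, 1):
            cfg = TrainConfig(iterations=3, seed=seed, val_every=100)
            _, _, log = fit(samples, None, GenConfig(**GEN_CFG),
                            DiscConfig(**DISC_CFG), cfg)
            logs.append([r["loss_seg"] for r in log])
        assert logs[0] != logs[1]

    def test_resume_continues_iteration_numbering(self, tmp_path):
        samples = _tiny_dataset(2)
        short = TrainConfig(iterations=3, seed=0, val_every=100,
                            checkpoint_every=100)
        gen, disc, log_a = fit(samples, None, GenConfig(**GEN_CFG),
                               DiscConfig(**DISC_CFG), short,
                               out_dir=tmp_path / "a")
        full = TrainConfig(iterations=6, seed=0, val_every=100)
        _, _, log_b = fit(samples, None, train_cfg=full,
                          resume_from=tmp_path / "a" / "checkpoint_last.npz")
        combined = [r["iteration"] for r in log_a] + [r["iteration"] for r in log_b]
        straight = TrainConfig(iterations=6, seed=0, val_every=100)
        _, _, log_c = fit(samples, None, GenConfig(**GEN_CFG),
                          DiscConfig(**DISC_CFG), straight)
        assert combined == [r["iteration"] for r in log_c] == list(range(1, 7))

    def test_run_directory_artifacts(self, tmp_path):
        samples = _tiny_dataset(3)
        cfg = TrainConfig(iterations=4, seed=0, val_every=2, checkpoint_every=2)
        fit(samples[:2], samples[2:], GenConfig(**GEN_CFG), DiscConfig(**DISC_CFG),
            cfg, out_dir=tmp_path / "run")
        run = tmp_path / "run"
        assert (run / "config.json").exists()
        assert (run / "checkpoint_last.npz").exists()
        assert (run / "checkpoint_000002.npz").exists()
        assert (run / "validation.csv").exists()
        lines = (run / "train_log.jsonl").read_text().strip().splitlines()
        assert len(lines) == 4


class TestCheckpoints:
    def test_round_trip_preserves_validation_metrics(self, tmp_path):
        samples = _tiny_dataset(3)
        cfg = TrainConfig(iterations=2, seed=0, val_every=100)
        gen, disc, _ = fit(samples[:2], None, GenConfig(**GEN_CFG),
                           DiscConfig(**DISC_CFG), cfg)
        pre = PreprocConfig()
        from sadgan.training import predict_sample
        before = predict_sample(gen, samples[2], pre)

        path = tmp_path / "ck.npz"
        save_checkpoint(path, gen, disc, 2, gen.cfg, disc.cfg)
        gen2, disc2, it = load_checkpoint(path)
        assert it == 2
        after = predict_sample(gen2, samples[2], pre)
        np.testing.assert_array_equal(before, after)
        assert disc2 is not None
        m = samples[2].vessel_mask.astype(np.float64)
        assert disc.score(m) == pytest.approx(disc2.score(m), abs=1e-7)

    def test_checkpoint_preserves_config(self, tmp_path):
        gen = Generator(GenConfig(base_channels=4, seed=3,
                                  plain_blocks=("enc2", "dec1")))
        path = tmp_path / "g.npz"
        save_checkpoint(path, gen, None, 0, gen.cfg, None)
        gen2, disc2, _ = load_checkpoint(path)
        assert disc2 is None
        assert gen2.cfg.plain_blocks == ("enc2", "dec1")
        assert gen2.cfg.base_channels == 4


def test_prepare_pair_pads_to_multiple(phantom_64):
    img, truth, crop = prepare_pair(phantom_64, PreprocConfig(), 16)
    assert img.shape[0] % 16 == 0 and img.shape[1] % 16 == 0
    assert img.shape == truth.shape
    assert set(np.unique(truth)) <= {0, 1}
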