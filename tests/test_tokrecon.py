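"""Token-reconstruction objective: corruption statistics, loss, schedule,
optimizer hygiene, and the training loop contract."""

import hashlib

import numpy as np
import pytest
from scipy.stats import kstest

from fundusfm.model import build_student, forward_tokens
from fundusfm.tokrecon import (AdamW, CorruptionSpec, TrainConfig,
                               add_pixel_noise, clip_gradients, lr_at_epoch,
                               sample_corruption_mask, sample_corruption_plan,
                               token_reconstruction_loss, train)


def _state_hash(model):
    h = hashlib.sha256()
    for k, v in sorted(model.state_dict().items()):
        h.update(k.encode())
        h.update(v.tobytes())
    return h.hexdigest()


class TestCorruptionMask:
    def test_zero_upper_gives_empty_mask(self, rng):
        spec = CorruptionSpec(ratio_upper=0.0)
        assert sample_corruption_mask(50, spec, rng).sum() == 0

    def test_fraction_never_exceeds_upper_bound(self, rng):
        """|mask|/n <= 1/3 + 1/n for every draw (rounding slack only)."""
        spec = CorruptionSpec()
        n = 49
        for _ in range(10_000):
            frac = sample_corruption_mask(n, spec, rng).mean()
            assert frac <= 1 / 3 + 1 / n

    def test_mean_fraction_and_ks_uniform(self, rng):
        """Mean masked fraction is E[U(0,1/3)] = 1/6 +- 0.01, and the sampled
        fractions pass a KS test against U(0, 1/3)."""
        spec = CorruptionSpec()
        n = 300
        fracs = np.array([sample_corruption_mask(n, spec, rng).mean()
                          for _ in range(10_000)])
        assert abs(fracs.mean() - 1 / 6) < 0.01
        stat, p = kstest(fracs, "uniform", args=(0, 1 / 3))
        assert p > 0.001

    def test_plan_keeps_last_image_clean(self, rng):
        plan = sample_corruption_plan(8, 40, CorruptionSpec(), rng)
        assert plan.masks.shape == (8, 40)
        assert not plan.masks[-1].any()
        assert not plan.noise_flags[-1]

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            CorruptionSpec(ratio_upper=1.5)
        with pytest.raises(ValueError):
            CorruptionSpec(noise_sigma=-0.1)


class TestPixelNoise:
    def test_sigma_zero_identity(self, rng):
        x = rng.normal(size=(10, 10, 3)).astype(np.float32)
        assert np.array_equal(add_pixel_noise(x, 0.0, rng), x)

    def test_noise_moments(self):
        """Empirical std of the added noise is 0.2 +- 0.005 and its mean is
        0 +- 0.003 over a million pixels."""
        rng = np.random.default_rng(0)
        x = np.zeros((1000, 1000), dtype=np.float32)
        diff = add_pixel_noise(x, 0.2, rng) - x
        assert abs(diff.std() - 0.2) < 0.005
        assert abs(diff.mean()) < 0.003


class TestLoss:
    def test_identical_tokens_zero(self, rng):
        t = rng.normal(size=(2, 9, 8))
        assert token_reconstruction_loss(t, t.copy()) == 0.0

    def test_constant_offset_closed_form(self, rng):
        t = rng.normal(size=(3, 7, 5))
        c = 0.37
        assert token_reconstruction_loss(t + c, t) == pytest.approx(c * c, rel=1e-6)

    def test_matches_brute_force(self, rng):
        a = rng.normal(size=(2, 11, 6))
        b = rng.normal(size=(2, 11, 6))
        brute = float(np.mean([(x - y) ** 2 for x, y in zip(a.ravel(), b.ravel())]))
        assert abs(token_reconstruction_loss(a, b) - brute) < 1e-10

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            token_reconstruction_loss(rng.normal(size=(2, 5, 3)),
                                      rng.normal(size=(2, 6, 3)))


class TestSchedule:
    def test_endpoints_and_midpoint(self):
        cfg = TrainConfig()
        assert lr_at_epoch(0, cfg) == 5e-9
        assert lr_at_epoch(10, cfg) == pytest.approx(5e-5)
        for e in range(100, 120):
            assert lr_at_epoch(e, cfg) == 5e-9
        # cosine midpoint of [10, 100] is epoch 55
        assert lr_at_epoch(55, cfg) == pytest.approx((5e-5 + 5e-9) / 2, abs=1e-12)

    def test_out_of_range_rejected(self):
        cfg = TrainConfig()
        for e in (-1, 120, 500):
            with pytest.raises(ValueError):
                lr_at_epoch(e, cfg)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=20, warmup_epochs=10, cooldown_epochs=10)
        with pytest.raises(ValueError):
            TrainConfig(min_lr=1.0, peak_lr=0.1)


class TestOptimizer:
    def test_no_weight_decay_on_biases(self, tiny_model):
        opt = AdamW(tiny_model.parameters(), TrainConfig())
        names = list(tiny_model.parameters())
        biases = [n for n in names if n.endswith("bias")]
        assert biases, "model should have bias parameters"
        assert all(not opt.decayed(n) for n in biases)
        assert all(opt.decayed(n) for n in names if not n.endswith("bias"))

    def test_clip_reduces_global_norm(self, tiny_config):
        model = build_student(tiny_config, seed=0)
        params = model.parameters()
        for p in params.values():
            p.grad = np.ones_like(p.data)
        norm = clip_gradients(params, 0.1)
        assert norm <= 0.1 + 1e-6
        total = np.sqrt(sum(float((p.grad ** 2).sum()) for p in params.values()))
        assert total == pytest.approx(0.1, rel=1e-5)


@pytest.fixture(scope="module")
def train_stack(small_dataset):
    from fundusfm.prep import GREEN_SCHEME, normalize, resize_image

    images, _ = small_dataset
    return np.stack([normalize(resize_image(im.pixels, (64, 64)), GREEN_SCHEME)
                     for im in images])


def _tiny_train_config(**kw):
    base = dict(epochs=16, batch_size=16, peak_lr=3e-3, min_lr=3e-6,
                warmup_epochs=2, cooldown_epochs=2, seed=0)
    base.update(kw)
    return TrainConfig(**base)


class TestTrainLoop:
    def test_step0_clean_batch_loss_exactly_zero(self, tiny_config, train_stack):
        """Frozen identical teacher + zero projector scale: an uncorrupted
        batch incurs exactly zero loss before any update."""
        model = build_student(tiny_config, seed=1)
        _, hist = train(train_stack[:8], model,
                        train_config=_tiny_train_config(batch_size=8),
                        corruption=CorruptionSpec(ratio_upper=0.0, noise_sigma=0.0),
                        n_steps=1, rng=np.random.default_rng(0))
        assert hist["loss"][0] == 0.0

    def test_teacher_parameters_unchanged(self, tiny_config, train_stack):
        student = build_student(tiny_config, seed=1)
        teacher = build_student(tiny_config, seed=1)
        before = _state_hash(teacher)
        train(train_stack[:32], student, teacher=teacher,
              train_config=_tiny_train_config(), n_steps=5,
              rng=np.random.default_rng(0))
        assert _state_hash(teacher) == before

    def test_training_reduces_corrupted_loss(self, tiny_config, train_stack):
        model = build_student(tiny_config, seed=1)
        _, hist = train(train_stack, model, train_config=_tiny_train_config(),
                        n_steps=60, rng=np.random.default_rng(0))
        assert np.mean(hist["loss"][-10:]) < 0.5 * hist["loss"][0]
        assert max(hist["grad_norm"]) <= 0.1 + 1e-6

    def test_same_seed_identical_loss_curves(self, tiny_config, train_stack):
        runs = []
        for _ in range(2):
            model = build_student(tiny_config, seed=1)
            _, hist = train(train_stack[:32], model,
                            train_config=_tiny_train_config(), n_steps=8,
                            rng=np.random.default_rng(7))
            runs.append(hist["loss"])
        assert runs[0] == runs[1]

    def test_teacher_shape_mismatch_rejected(self, tiny_config, train_stack):
        from fundusfm.model import BackboneConfig

        student = build_student(tiny_config, seed=1)
        other = build_student(BackboneConfig(image_side=64, patch_side=8,
                                             embed_dim=16, depth=2, heads=2), seed=1)
        with pytest.raises(ValueError, match="mismatch"):
            train(train_stack[:8], student, teacher=other,
                  train_config=_tiny_train_config(), n_steps=1)
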