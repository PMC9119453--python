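"""Objectives, augmentation, the alternating update scheme and inference."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from sweeprestore import nn
from sweeprestore.models import (DiscriminatorSpec, GeneratorSpec,
                                 build_discriminator, build_generator)
from sweeprestore.optics import ImagePair
from sweeprestore.training import (TrainSpec, augment, discriminator_loss,
                                   generator_loss, inverse_log_transform,
                                   l1_loss, load_checkpoint, log_transform,
                                   predict, sample_real_labels, save_checkpoint,
                                   train)

TOY_GEN = GeneratorSpec(depth=1, base_channels=4)


def smooth_image(rng, shape=(32, 32), scale=200.0):
    x = gaussian_filter(rng.random(shape), 2.0)
    x = (x - x.min()) / (x.max() - x.min() + 1e-9)
    return scale * x


class TestLogTransform:
    def test_zero_image_maps_to_zero(self):
        np.testing.assert_array_equal(log_transform(np.zeros((4, 4))), 0.0)

    def test_roundtrip(self):
        rng = np.random.default_rng(0)
        x = rng.random((8, 8)) * 1e4
        np.testing.assert_allclose(inverse_log_transform(log_transform(x)), x,
                                   rtol=1e-9)

    def test_closed_form_value(self):
        assert log_transform(np.array([np.e - 1.0]))[0] == pytest.approx(1.0)

    def test_negative_pixels_rejected(self):
        with pytest.raises(ValueError):
            log_transform(np.array([-1.0]))


class TestAugment:
    def test_dataset_bookkeeping_344_and_40(self):
        """86 training pairs and 10 validation pairs at 4 crops each."""
        rng = np.random.default_rng(0)
        spec = TrainSpec(crop_size=8, crops_per_image=4)
        pair = ImagePair(S=np.ones((16, 16)), P=np.ones((16, 16)))
        train_crops = [c for _ in range(86) for c in augment(pair, spec, rng)]
        val_crops = [c for _ in range(10) for c in augment(pair, spec, rng)]
        assert len(train_crops) == 344
        assert len(val_crops) == 40

    def test_matched_crops_preserve_pixelwise_relation(self):
        rng = np.random.default_rng(1)
        s = rng.random((20, 20)) * 50
        pair = ImagePair(S=s, P=2.0 * s)
        spec = TrainSpec(crop_size=8, crops_per_image=6, flip_prob=0.5)
        for crop in augment(pair, spec, rng):
            np.testing.assert_array_equal(crop.P, 2.0 * crop.S)
            assert crop.S.shape == (8, 8)

    def test_deterministic_given_seed(self):
        pair = ImagePair(S=np.arange(64.0).reshape(8, 8),
                         P=np.arange(64.0).reshape(8, 8))
        spec = TrainSpec(crop_size=4, crops_per_image=3)
        a = augment(pair, spec, np.random.default_rng(5))
        b = augment(pair, spec, np.random.default_rng(5))
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.S, cb.S)

    def test_oversized_crop_rejected(self):
        pair = ImagePair(S=np.zeros((8, 8)), P=np.zeros((8, 8)))
        with pytest.raises(ValueError):
            augment(pair, TrainSpec(crop_size=16), np.random.default_rng(0))


class TestLosses:
    def test_l1_identities_and_oracle(self):
        rng = np.random.default_rng(0)
        p = rng.random((5, 5))
        assert l1_loss(p, p) == 0.0
        assert l1_loss(np.zeros((2, 2)), np.ones((2, 2))) == 4.0
        q = rng.random((5, 5))
        oracle = sum(abs(p[i, j] - q[i, j]) for i in range(5) for j in range(5))
        assert abs(l1_loss(p, q) - oracle) < 1e-9

    def test_generator_loss_reduces_to_l1_when_d_equals_r(self):
        rng = np.random.default_rng(1)
        p, p_hat = rng.random((6, 6)), rng.random((6, 6))
        r = 1.0 - rng.uniform(0, 0.1, (3, 3))
        loss = generator_loss(r.copy(), p, p_hat, r, lambda_l1=10.0)
        assert loss == pytest.approx(10.0 * l1_loss(p, p_hat), abs=1e-12)

    def test_generator_loss_adversarial_unit_case(self):
        p = np.random.default_rng(2).random((4, 4))
        loss = generator_loss(np.zeros((3, 3)), p, p.copy(), np.ones((3, 3)), 10.0)
        assert loss == pytest.approx(1.0)

    def test_discriminator_loss_identities(self):
        r = np.full((3, 3), 0.95)
        f = np.zeros((3, 3))
        assert discriminator_loss(r.copy(), f.copy(), r, f) == 0.0
        assert discriminator_loss(np.zeros((2, 2)), np.ones((2, 2)),
                                  np.ones((2, 2)), np.zeros((2, 2))) == pytest.approx(1.0)

    def test_losses_match_straight_line_oracles(self):
        rng = np.random.default_rng(3)
        p, p_hat = rng.random((7, 7)), rng.random((7, 7))
        dr, df = rng.random((4, 4)), rng.random((4, 4))
        r, f = 1.0 - rng.uniform(0, 0.1, (4, 4)), np.zeros((4, 4))
        lam = 10.0
        g_oracle = lam * np.abs(p - p_hat).sum() + np.mean((df - r) ** 2)
        d_oracle = 0.5 * (np.mean((dr - r) ** 2) + np.mean((df - f) ** 2))
        assert abs(generator_loss(df, p, p_hat, r, lam) - g_oracle) < 1e-9
        assert abs(discriminator_loss(dr, df, r, f) - d_oracle) < 1e-9

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            l1_loss(np.zeros((2, 2)), np.zeros((3, 3)))
        with pytest.raises(ValueError):
            discriminator_loss(np.zeros((2, 2)), np.zeros((2, 2)),
                               np.zeros((3, 3)), np.zeros((2, 2)))

    def test_adversarial_gradient_vanishes_at_optimum(self):
        """With lambda_L1 = 0 and D output equal to R, the generator objective
        is at a stationary point of the prediction."""
        rng = np.random.default_rng(4)
        p = rng.random((4, 4))
        p_hat = nn.Tensor(rng.random((4, 4)), requires_grad=True)
        r = 1.0 - rng.uniform(0, 0.1, (2, 2))
        d_fake = nn.Tensor(r.copy(), requires_grad=True)
        loss = generator_loss(d_fake, nn.Tensor(p), p_hat, r, lambda_l1=0.0)
        loss.backward()
        np.testing.assert_allclose(d_fake.grad, 0.0)
        assert p_hat.grad is None or np.allclose(p_hat.grad, 0.0)


class TestLabelSmoothing:
    def test_width_zero_gives_exact_ones(self):
        labels = sample_real_labels((4, 4), 0.0, np.random.default_rng(0))
        np.testing.assert_array_equal(labels.R, 1.0)
        np.testing.assert_array_equal(labels.F, 0.0)

    def test_uniform_moments_at_width_point_one(self):
        labels = sample_real_labels((100, 100), 0.1, np.random.default_rng(1))
        n = labels.R.size
        assert labels.R.min() >= 0.9
        assert labels.R.max() <= 1.0
        se = (0.1 / np.sqrt(12)) / np.sqrt(n)
        assert abs(labels.R.mean() - 0.95) < 3 * se

    def test_fresh_draw_per_call(self):
        rng = np.random.default_rng(2)
        a = sample_real_labels((3, 3), 0.1, rng)
        b = sample_real_labels((3, 3), 0.1, rng)
        assert np.any(a.R != b.R)


class TestTrainLoop:
    def test_identity_task_reduces_validation_l1(self):
        rng = np.random.default_rng(3)
        pairs = [ImagePair(S=(s := smooth_image(rng)), P=s.copy()) for _ in range(8)]
        spec = TrainSpec(max_epochs=20, crop_size=32, crops_per_image=1,
                         learning_rate=0.01, seed=1)
        ckpt, hist = train(pairs[:6], pairs[6:], TOY_GEN, spec)
        assert hist["val_l1"][-1] < hist["val_l1"][0]
        assert ckpt.validation_l1 == min(hist["val_l1"])

    def test_deterministic_transform_task_beats_identity_by_10x(self):
        """P = 0.6 S (noiseless): a small generator reaches validation L1
        below 10% of the identity baseline."""
        rng = np.random.default_rng(3)
        pairs = [ImagePair(S=(s := smooth_image(rng)), P=0.6 * s)
                 for _ in range(10)]
        baseline = np.mean([np.abs(log_transform(p.P) - log_transform(p.S)).sum()
                            for p in pairs[8:]])
        spec = TrainSpec(max_epochs=300, crop_size=32, crops_per_image=2,
                         learning_rate=0.02, seed=1)
        ckpt, _ = train(pairs[:8], pairs[8:], TOY_GEN, spec)
        assert ckpt.validation_l1 < 0.1 * baseline

    def test_phase_freezing_contract(self):
        """Generator step leaves discriminator weights bit-identical and
        vice versa (alternating-phase audit)."""
        rng = np.random.default_rng(6)
        gen = build_generator(TOY_GEN, seed=0)
        disc = build_discriminator(DiscriminatorSpec(channels=(4, 8, 8, 8, 1)), seed=1)
        gen_opt = nn.Adam(gen.parameters(), lr=1e-3)
        disc_opt = nn.Adam(disc.parameters(), lr=1e-3)
        s = nn.Tensor(rng.random((2, 1, 64, 64)))
        p = nn.Tensor(rng.random((2, 1, 64, 64)))

        disc_before = {k: v.copy() for k, v in disc.state_dict().items()}
        gen.zero_grad()
        p_hat = gen(s)
        d_fake = disc(s, p_hat)
        labels = sample_real_labels(d_fake.shape, 0.1, rng)
        generator_loss(d_fake, p, p_hat, labels.R, 10.0).backward()
        gen_opt.step()
        for k, v in disc.state_dict().items():
            if not k.startswith("buffer:"):
                np.testing.assert_array_equal(v, disc_before[k])

        gen_before = {k: v.copy() for k, v in gen.state_dict().items()}
        disc.zero_grad()
        d_real = disc(s, p)
        d_fake = disc(s, p_hat.detach())
        labels = sample_real_labels(d_real.shape, 0.1, rng)
        discriminator_loss(d_real, d_fake, labels.R, labels.F).backward()
        disc_opt.step()
        for k, v in gen.state_dict().items():
            if not k.startswith("buffer:"):
                np.testing.assert_array_equal(v, gen_before[k])

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train([], [], TOY_GEN, TrainSpec())

    def test_config_defaults_match_study_settings(self):
        spec = TrainSpec()
        assert spec.lambda_l1 == 10.0
        assert spec.learning_rate == 2e-4
        assert spec.batch_size == 2
        assert spec.max_epochs == 1250
        assert spec.label_smoothing_width == 0.1
        assert spec.crop_size == 256
        assert spec.flip_prob == 0.25


@pytest.fixture(scope="module")
def toy_checkpoint():
    rng = np.random.default_rng(9)
    pairs = [ImagePair(S=(s := smooth_image(rng)), P=s.copy()) for _ in range(4)]
    spec = TrainSpec(max_epochs=2, crop_size=32, crops_per_image=1,
                     learning_rate=0.01, seed=0)
    ckpt, _ = train(pairs[:3], pairs[3:], TOY_GEN, spec)
    return ckpt


class TestPredict:
    def test_inference_deterministic_and_nonnegative(self, toy_checkpoint):
        x = smooth_image(np.random.default_rng(10))
        a = predict(toy_checkpoint, x)
        b = predict(toy_checkpoint, x)
        np.testing.assert_array_equal(a, b)
        assert np.isfinite(a).all()
        assert (a >= 0).all()

    def test_non_divisible_input_is_padded_and_cropped(self, toy_checkpoint):
        x = smooth_image(np.random.default_rng(11), shape=(30, 35))
        out = predict(toy_checkpoint, x)
        assert out.shape == (30, 35)

    def test_checkpoint_roundtrip(self, toy_checkpoint, tmp_path):
        path = tmp_path / "gen.npz"
        save_checkpoint(toy_checkpoint, path)
        loaded = load_checkpoint(path)
        x = smooth_image(np.random.default_rng(12))
        np.testing.assert_array_equal(predict(loaded, x),
                                      predict(toy_checkpoint, x))
        assert loaded.generator_spec == toy_checkpoint.generator_spec
        assert loaded.validation_l1 == pytest.approx(toy_checkpoint.validation_l1)
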