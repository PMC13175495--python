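"""Conditional GAN: architecture contracts, losses, augmentation, training
behaviour and sliding-window inference."""

import numpy as np
import pytest

from datgen import gan, nn
from datgen.gan import (AugmentConfig, DiscriminatorConfig, GeneratorConfig,
                        LossWeights, TrainConfig, augment, build_discriminator,
                        build_generator, gan_loss, generate_volume, l1_loss,
                        sample_augment_params, total_loss, train)
from datgen.preprocess import TrainingSample


def tiny_samples(n, channels=4, size=16, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        x = rng.normal(size=(channels, size, size)).astype(np.float32)
        y = np.tanh(x[:2].mean(axis=0)).astype(np.float32)
        out.append(TrainingSample(x, y, i))
    return out


TINY_G = GeneratorConfig(in_channels=4, base_filters=4, depth=2)


class TestGenerator:
    def test_output_shape_matches_input(self):
        g = build_generator(GeneratorConfig(in_channels=75, base_filters=4),
                            seed=0)
        out = g.forward(np.zeros((1, 75, 64, 64), dtype=np.float32),
                        train=False)
        assert out.shape == (1, 1, 64, 64)

    def test_outputs_strictly_inside_unit_interval(self):
        g = build_generator(TINY_G, seed=1)
        rng = np.random.default_rng(0)
        out = g.forward(rng.normal(size=(1, 4, 16, 16)).astype(np.float32),
                        train=False)
        assert np.all(out > -1.0) and np.all(out < 1.0)

    def test_depth4_bottleneck_is_4x4(self):
        """64x64 through four stride-2 encoders bottoms out at 4x4, below
        the 64x64 dropout threshold."""
        g = build_generator(GeneratorConfig(in_channels=2, base_filters=2),
                            seed=0)
        x = np.zeros((1, 2, 64, 64), dtype=np.float32)
        for blk in g.enc:
            for l in blk:
                x = l.forward(x, train=False)
        assert x.shape[-2:] == (4, 4)

    def test_indivisible_dims_raise(self):
        g = build_generator(TINY_G, seed=0)
        with pytest.raises(ValueError, match="divisible"):
            g.forward(np.zeros((1, 4, 18, 18), dtype=np.float32))

    def test_wrong_channel_count_raises(self):
        g = build_generator(TINY_G, seed=0)
        with pytest.raises(ValueError, match="channels"):
            g.forward(np.zeros((1, 3, 16, 16), dtype=np.float32))

    def test_end_to_end_gradient_matches_finite_difference(self):
        from .test_nn import numeric_grad
        cfg = GeneratorConfig(in_channels=2, base_filters=3, depth=2,
                              dropout_rate=0.0)
        g = build_generator(cfg, seed=1)
        x = np.random.default_rng(2).normal(size=(1, 2, 8, 8)).astype(np.float32)
        w = np.random.default_rng(3).normal(size=(1, 1, 8, 8))

        def loss():
            return float((g.forward(x, train=False).astype(np.float64) * w).sum())

        g.forward(x, train=False)
        for p in g.params():
            p.grad[...] = 0.0
        gin = g.backward(w.astype(np.float32))
        # small eps: the loss surface is kinked (LeakyReLU) and curved
        # (InstanceNorm), so larger steps pick up curvature error
        assert np.abs(gin - numeric_grad(loss, x, eps=2.5e-4)).max() < 5e-3
        p0 = g.params()[0]
        assert np.abs(p0.grad - numeric_grad(loss, p0.data, eps=2.5e-4)).max() < 5e-3


class TestDiscriminator:
    def test_emits_score_map(self):
        d = build_discriminator(DiscriminatorConfig(in_channels=5,
                                                    base_filters=4), seed=0)
        cond = np.zeros((1, 4, 16, 16), dtype=np.float32)
        sl = np.zeros((1, 1, 16, 16), dtype=np.float32)
        scores = d.forward(cond, sl)
        assert scores.ndim == 4 and scores.shape[1] == 1
        assert scores.shape[-1] > 1  # patch map, not a single logit

    def test_slice_gradient_matches_finite_difference(self):
        from .test_nn import numeric_grad
        d = build_discriminator(DiscriminatorConfig(in_channels=3,
                                                    base_filters=4), seed=0)
        rng = np.random.default_rng(4)
        cond = rng.normal(size=(1, 2, 16, 16)).astype(np.float32)
        sl = rng.normal(size=(1, 1, 16, 16)).astype(np.float32)

        def loss():
            return nn.bce_with_logits(d.forward(cond, sl, train=False), 1.0)[0]

        scores = d.forward(cond, sl, train=False)
        _, gs = nn.bce_with_logits(scores, 1.0)
        gslice = d.backward(gs)
        assert np.abs(gslice - numeric_grad(loss, sl)).max() < 1e-3


class TestLosses:
    def test_l1_identical_is_zero(self, rng):
        a = rng.normal(size=(8, 8)).astype(np.float32)
        assert l1_loss(a, a.copy()) == 0.0

    def test_l1_constant_offset(self, rng):
        a = rng.normal(size=(8, 8)).astype(np.float32)
        assert l1_loss(a + 0.5, a) == pytest.approx(0.5, rel=1e-5)

    def test_l1_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            l1_loss(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_gan_loss_ln2_at_zero_logits(self):
        scores = np.zeros((1, 1, 4, 4), dtype=np.float32)
        assert gan_loss(scores, is_real=True) == pytest.approx(np.log(2.0))
        assert gan_loss(scores, is_real=False) == pytest.approx(np.log(2.0))

    def test_total_loss_weighted_sum(self):
        assert total_loss(0.7, 0.02) == pytest.approx(0.7 + 2.0)
        assert total_loss(0.7, 0.02, LossWeights(lambda_l1=0.0)) == \
            pytest.approx(0.7)
        assert total_loss(0.7, 0.5, LossWeights(lambda_gan=0.0)) == \
            pytest.approx(50.0)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(lambda_gan=-1.0)


class TestAugment:
    def test_identity_transform_preserves_sample(self):
        s = tiny_samples(1)[0]

        class FixedRng:
            def uniform(self, lo, hi):
                return 0.0 if lo < 0 else 1.0

        out = augment(s, FixedRng(), AugmentConfig(scale_range=(1.0, 1.0)))
        assert np.array_equal(out.input_stack, s.input_stack)
        assert np.array_equal(out.target_slice, s.target_slice)

    def test_same_rng_state_reproducible(self):
        s = tiny_samples(1)[0]
        a = augment(s, np.random.default_rng(5))
        b = augment(s, np.random.default_rng(5))
        assert np.array_equal(a.input_stack, b.input_stack)
        assert np.array_equal(a.target_slice, b.target_slice)

    def test_all_channels_share_the_transform(self):
        """Duplicated channels must stay identical after augmentation."""
        rng = np.random.default_rng(6)
        plane = rng.normal(size=(16, 16)).astype(np.float32)
        s = TrainingSample(np.stack([plane, plane]), plane.copy(), 0)
        out = augment(s, np.random.default_rng(7))
        assert np.array_equal(out.input_stack[0], out.input_stack[1])
        assert np.array_equal(out.input_stack[0], out.target_slice)

    def test_sampled_parameters_within_bounds(self):
        rng = np.random.default_rng(8)
        cfg = AugmentConfig()
        rots, shears, scales = [], [], []
        for _ in range(10_000):
            p = sample_augment_params(rng, cfg)
            rots.append(p["rotation_deg"])
            shears.append(p["shear_deg"])
            scales.append(p["scale"])
        assert -10.0 <= min(rots) and max(rots) <= 10.0
        assert -5.0 <= min(shears) and max(shears) <= 5.0
        assert 0.95 <= min(scales) and max(scales) <= 1.05
        assert max(rots) > 9.0 and min(rots) < -9.0  # ranges are exercised


class TestTrain:
    def test_empty_dataset_raises(self):
        with pytest.raises(ValueError, match="empty"):
            train([], TINY_G)

    def test_training_deterministic_under_seed(self):
        samples = tiny_samples(4)
        kw = dict(gcfg=TINY_G, tcfg=TrainConfig(epochs=3, seed=11))
        m1 = train(samples, **kw)
        m2 = train(samples, **kw)
        assert m1.history == m2.history
        for p1, p2 in zip(m1.generator.params(), m2.generator.params()):
            assert np.array_equal(p1.data, p2.data)

    def test_single_sample_overfit_reduces_l1(self):
        """200 optimisation steps on one sample must reduce L1."""
        samples = tiny_samples(1)
        m = train(samples, TINY_G,
                  tcfg=TrainConfig(epochs=200, seed=0, augment=False))
        assert m.history["l1"][-1] < m.history["l1"][0]
        assert m.history["l1"][-1] < 0.9 * m.history["l1"][0]

    def test_pure_l1_regression_at_zero_gan_weight(self):
        """With lambda_GAN = 0 training reduces to L1 regression, which on a
        single sample converges at least as low as the adversarial run."""
        samples = tiny_samples(1, seed=2)
        tcfg = TrainConfig(epochs=150, seed=0, augment=False)
        m_l1 = train(samples, TINY_G, w=LossWeights(lambda_gan=0.0), tcfg=tcfg)
        m_gan = train(samples, TINY_G, w=LossWeights(), tcfg=tcfg)
        tol = 0.02  # convergence tolerance on the mean-absolute-error scale
        assert m_l1.history["l1"][-1] <= m_gan.history["l1"][-1] + tol

    def test_l1_term_dominates_total_early(self):
        """With default weights the weighted L1 term carries the majority of
        the generator objective in the first epochs."""
        samples = tiny_samples(4, seed=3)
        m = train(samples, TINY_G, tcfg=TrainConfig(epochs=2, seed=1))
        for l1, g in zip(m.history["l1"][:2], m.history["gan"][:2]):
            assert 100.0 * l1 > g

    def test_history_lengths_match_epochs(self):
        m = train(tiny_samples(2), TINY_G, tcfg=TrainConfig(epochs=3, seed=0))
        assert all(len(v) == 3 for v in m.history.values())


@pytest.fixture(scope="module")
def model_and_prepared():
    from datgen import preprocess, phantom
    study = phantom.simulate_study(phantom.PhantomSpec(seed=9))
    cfg = preprocess.PreprocessConfig.for_phantom()
    prepared = preprocess.prepare_study(study, cfg)
    gcfg = GeneratorConfig(in_channels=75, base_filters=4)
    model = gan.GanModel(build_generator(gcfg, seed=0),
                         build_discriminator(
                             DiscriminatorConfig(in_channels=76,
                                                 base_filters=4), seed=0),
                         gcfg, DiscriminatorConfig(in_channels=76),
                         LossWeights())
    return model, prepared


class TestGenerateVolume:

    def test_output_shape_equals_slab_shape(self, model_and_prepared):
        model, prepared = model_and_prepared
        vol = generate_volume(model, prepared)
        assert vol.shape == prepared.delayed_scaled.shape

    def test_output_within_suvr_range(self, model_and_prepared):
        model, prepared = model_and_prepared
        vol = generate_volume(model, prepared)
        assert vol.min() > 0.0 and vol.max() < 10.0

    def test_constant_input_gives_identical_slices(self):
        """Identical conditioning stacks must produce identical predictions
        (functional determinism of inference)."""
        from datgen.preprocess import PreparedStudy
        const = np.full((75, 12, 16, 16), 0.3, dtype=np.float32)
        prepared = PreparedStudy(early_channels=const[:15],
                                 delayed_scaled=np.zeros((12, 16, 16),
                                                         dtype=np.float32),
                                 slab=slice(0, 12), scale_ranges=[(0.0, 1.0)],
                                 voxel_mm=2.0)
        gcfg = GeneratorConfig(in_channels=75, base_filters=4)
        model = gan.GanModel(build_generator(gcfg, seed=3),
                             build_discriminator(
                                 DiscriminatorConfig(in_channels=76,
                                                     base_filters=4), seed=3),
                             gcfg, DiscriminatorConfig(in_channels=76),
                             LossWeights())
        vol = generate_volume(model, prepared)
        for z in range(1, vol.shape[0]):
            assert np.array_equal(vol[z], vol[0])

    def test_channel_mismatch_raises(self, model_and_prepared):
        model, prepared = model_and_prepared
        bad = gan.GeneratorConfig(in_channels=15, base_filters=4)
        bad_model = gan.GanModel(build_generator(bad, seed=0),
                                 model.discriminator, bad,
                                 model.dcfg, LossWeights())
        with pytest.raises(ValueError, match="channels"):
            generate_volume(bad_model, prepared)


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path):
        samples = tiny_samples(2)
        m = train(samples, TINY_G, tcfg=TrainConfig(epochs=1, seed=0))
        m.save(str(tmp_path / "model"))
        loaded = gan.GanModel.load(str(tmp_path / "model"))
        x = samples[0].input_stack[None]
        assert np.array_equal(m.generator.forward(x, train=False),
                              loaded.generator.forward(x, train=False))
        assert loaded.history["l1"] == m.history["l1"]
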