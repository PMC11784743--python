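import numpy as np
import pytest

from hatl.autodiff import Tensor, grad
from hatl.data import get_profile
from hatl.gan import (Discriminator, DiscriminatorSpec, Generator,
                      GeneratorSpec, TrainConfig, adversarial_losses,
                      default_specs, discriminator_forward, generator_forward,
                      gradient_penalty, synthesize_eeg, train_hatl)
from hatl.fidelity import euclidean_rowwise
from hatl.simulate import SimConfig, simulate_multimodal_features


class TestSpecs:
    def test_seedv_concatenative_width_law(self):
        # input 32 + 33 + 5 = 70; blocks 64/128/256 each concatenate their
        # output, so the head sees 70 + 64 + 128 + 256 = 518
        spec = GeneratorSpec(block_units=(64, 128, 256), noise_dim=32,
                             label_dim=5, cond_dim=33, out_dim=310)
        assert spec.in_dim == 70
        assert [spec.block_input_width(k) for k in range(4)] == [70, 134, 262, 518]
        assert spec.final_in_dim == 518

    def test_parameter_count_matches_width_recurrence(self, rng):
        for blocks in [(8,), (16, 8), (64, 128, 256)]:
            spec = GeneratorSpec(block_units=blocks, noise_dim=4, label_dim=3,
                                 cond_dim=5, out_dim=7)
            gen = Generator(spec, rng)
            expected = 0
            w = spec.in_dim
            for u in blocks:
                expected += w * u + u   # linear
                expected += 2 * u       # batch-norm gamma/beta
                w += u
            expected += w * 7 + 7       # head
            assert gen.n_params == expected

    def test_invalid_dimensions(self):
        with pytest.raises(ValueError):
            GeneratorSpec(block_units=(0,), noise_dim=4, label_dim=2,
                          cond_dim=3, out_dim=5)
        with pytest.raises(ValueError):
            DiscriminatorSpec(layer_units=(8, -1), in_dim=10)

    def test_default_specs_per_profile(self):
        cfg = TrainConfig()
        g, d = default_specs(get_profile("seedv"), 5, cfg)
        assert g.block_units == (64, 128, 256) and d.layer_units == (128, 64)
        g, d = default_specs(get_profile("deap"), 4, cfg)
        assert g.block_units == (128, 128) and d.layer_units == (64, 64)
        g, d = default_specs(get_profile("graffitivr"), 4, cfg)
        assert g.block_units == (64, 64) and d.layer_units == (32, 32)


class TestForwardPasses:
    def test_generator_shapes_and_determinism(self, quick_model, rng):
        n = 7
        z = rng.normal(size=(n, quick_model.gen_spec.noise_dim))
        s = rng.random((n, 4))
        y = rng.integers(0, 4, size=n)
        out1 = generator_forward(quick_model, z, s, y)
        out2 = generator_forward(quick_model, z, s, y)
        assert out1.shape == (n, 8)
        assert np.array_equal(out1, out2)

    def test_generator_dim_mismatch(self, quick_model, rng):
        with pytest.raises(ValueError):
            generator_forward(quick_model, rng.normal(size=(3, 2)),
                              rng.random((3, 4)), [0, 1, 2])

    def test_cgan_scores_in_unit_interval(self, scaled_mini, rng):
        model = train_hatl(scaled_mini, "cgan", TrainConfig(epochs=1, seed=0))
        scores = discriminator_forward(model, rng.random((20, 8)),
                                       rng.integers(0, 4, 20))
        assert np.all((scores > 0) & (scores < 1))

    def test_wasserstein_scores_unbounded(self, quick_model, rng):
        scores = discriminator_forward(quick_model, 100 * rng.random((20, 8)),
                                       rng.integers(0, 4, 20))
        assert scores.shape == (20,)  # raw critic values, no squashing

    def test_zeroed_head_gives_zero_logit(self, rng):
        spec = DiscriminatorSpec(layer_units=(8, 8), in_dim=12)
        disc = Discriminator(spec, rng)
        disc.head.W.data[:] = 0.0
        disc.head.b.data[:] = 0.0
        out = disc.forward(Tensor(rng.normal(size=(5, 8))),
                           Tensor(np.eye(4)[[0, 1, 2, 3, 0]]), training=False)
        assert np.all(out.data == 0.0)


class TestAdversarialLosses:
    def test_cgan_half_scores_closed_form(self):
        d, g = adversarial_losses("cgan", np.full(4, 0.5), np.full(4, 0.5))
        assert d == pytest.approx(2 * np.log(2))
        assert g == pytest.approx(np.log(2))

    def test_cwgan_closed_form(self):
        d, g = adversarial_losses("cwgan", np.array([2.0, 2.0]), np.array([1.0, 1.0]))
        assert d == pytest.approx(-1.0) and g == pytest.approx(-1.0)

    def test_random_scores_match_direct_formulas(self, rng):
        r = rng.uniform(0.01, 0.99, 10)
        f = rng.uniform(0.01, 0.99, 10)
        d, g = adversarial_losses("cgan", r, f)
        assert d == pytest.approx(-(np.log(r).mean() + np.log(1 - f).mean()))
        assert g == pytest.approx(-np.log(f).mean())
        r2, f2 = rng.normal(size=8), rng.normal(size=8)
        d2, g2 = adversarial_losses("cwgan-gp", r2, f2)
        assert d2 == pytest.approx(f2.mean() - r2.mean())
        assert g2 == pytest.approx(-f2.mean())

    def test_cgan_rejects_out_of_range_scores(self):
        with pytest.raises(ValueError):
            adversarial_losses("cgan", np.array([1.5]), np.array([0.5]))

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            adversarial_losses("cwgan", np.array([]), np.array([1.0]))


class TestGradientPenalty:
    def _linear_model(self, w, quick_model):
        """Overwrite the quick model's critic with a pure linear map w.x."""
        import copy
        m = copy.deepcopy(quick_model)
        for lin in m.discriminator.layers:
            # identity-ish passthrough: large positive slope region
            lin.W.data[:] = 0.0
            lin.b.data[:] = 1.0
        return m

    def test_unit_gradient_zero_penalty(self, rng):
        # single-layer critic behaving as w.x with ||w|| = 1 on the x block
        from hatl.gan import HatlModel
        spec = DiscriminatorSpec(layer_units=(8,), in_dim=12)
        disc = Discriminator(spec, rng)
        # route: first layer = identity on x (slope>0), head = unit vector
        disc.layers[0].W.data[:] = 0.0
        disc.layers[0].W.data[:8, :8] = np.eye(8)
        disc.layers[0].b.data[:] = 10.0  # keep LeakyReLU in its linear region
        w = rng.normal(size=8)
        w /= np.linalg.norm(w)
        disc.head.W.data = w[:, None]
        disc.head.b.data[:] = 0.0
        gspec = GeneratorSpec(block_units=(8,), noise_dim=2, label_dim=4,
                              cond_dim=4, out_dim=8)
        model = HatlModel("cwgan-gp", Generator(gspec, rng), disc, gspec, spec,
                          TrainConfig(), "h", 4)
        x_real = rng.random((6, 8))
        x_fake = rng.random((6, 8))
        y = rng.integers(0, 4, 6)
        assert gradient_penalty(model, x_real, x_fake, y, 10.0) == pytest.approx(0.0, abs=1e-9)
        # scaling the head by 3 gives gradient norm 3: penalty 10 * (3-1)^2
        disc.head.W.data = 3 * w[:, None]
        assert gradient_penalty(model, x_real, x_fake, y, 10.0) == pytest.approx(40.0, abs=1e-6)

    def test_gradient_norm_matches_finite_differences(self, quick_model, rng):
        x = rng.random((4, 8))
        yh = np.eye(4)[rng.integers(0, 4, 4)]
        disc = quick_model.discriminator
        xt = Tensor(x)
        out = disc.forward(xt, Tensor(yh), training=False).sum()
        g, = grad(out, [xt])
        eps = 1e-5
        fd = np.zeros_like(x)
        for i in range(4):
            for j in range(8):
                xp, xm = x.copy(), x.copy()
                xp[i, j] += eps
                xm[i, j] -= eps
                op = disc.forward(Tensor(xp), Tensor(yh), False).data.sum()
                om = disc.forward(Tensor(xm), Tensor(yh), False).data.sum()
                fd[i, j] = (op - om) / (2 * eps)
        assert np.allclose(g.data, fd, atol=1e-4)

    def test_negative_lambda_rejected(self, quick_model, rng):
        with pytest.raises(ValueError):
            gradient_penalty(quick_model, rng.random((3, 8)),
                             rng.random((3, 8)), [0, 1, 2], -1.0)


class TestTraining:
    def test_unscaled_data_rejected(self, mini_ds):
        with pytest.raises(ValueError, match="scaled"):
            train_hatl(mini_ds, "cwgan-gp", TrainConfig(epochs=1))

    def test_single_class_rejected(self, scaled_mini):
        one = scaled_mini.rows(scaled_mini.y == 0)
        with pytest.raises(ValueError, match="class"):
            train_hatl(one, "cwgan-gp", TrainConfig(epochs=1))

    def test_zero_epochs_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)

    def test_same_seed_identical_history(self, scaled_mini):
        cfg = TrainConfig(epochs=2, batch_size=32, seed=11)
        m1 = train_hatl(scaled_mini, "cwgan-gp", cfg)
        m2 = train_hatl(scaled_mini, "cwgan-gp", cfg)
        assert m1.history == m2.history

    def test_history_lengths_and_variant_tag(self, quick_model):
        assert quick_model.variant == "cwgan-gp"
        assert quick_model.trained
        for key in ("d_loss", "g_loss", "euclidean", "wasserstein"):
            assert len(quick_model.history[key]) == quick_model.config.epochs

    def test_cwgan_weights_clipped(self, scaled_mini):
        cfg = TrainConfig(epochs=2, batch_size=32, seed=0)
        m = train_hatl(scaled_mini, "cwgan", cfg)
        for p in m.discriminator.params:
            assert np.all(np.abs(p.data) <= cfg.clip_value + 1e-12)

    def test_uncoupled_data_no_hallucinated_signal(self):
        # with coupling 0 the generator cannot beat a same-class shuffled
        # pairing of real rows (no cross-modal signal to exploit)
        margins = []
        for seed in range(5):
            ds = simulate_multimodal_features(
                SimConfig(seed=seed, coupling=0.0, rows_per_subject=80))
            scaled = ds.scale()
            m = train_hatl(scaled, "cwgan-gp",
                           TrainConfig(epochs=15, batch_size=32, seed=seed))
            hold = m.holdout_idx
            x_hold, y_hold = scaled.X_eeg[hold], scaled.y[hold]
            rng = np.random.default_rng(seed)
            x_shuf = x_hold.copy()
            for c in np.unique(y_hold):
                idx = np.flatnonzero(y_hold == c)
                x_shuf[idx] = x_hold[rng.permutation(idx)]
            baseline, _ = euclidean_rowwise(x_hold, x_shuf, y_hold)
            margins.append(m.history["euclidean"][-1] - baseline)
        assert np.mean(margins) > -0.05  # no better than baseline, within MC noise


class TestSynthesize:
    def test_untrained_model_rejected(self, scaled_mini, rng):
        from hatl.gan import HatlModel
        cfg = TrainConfig(epochs=1)
        gspec, dspec = default_specs(scaled_mini.schema, 4, cfg)
        g = np.random.default_rng(0)
        m = HatlModel("cwgan-gp", Generator(gspec, g), Discriminator(dspec, g),
                      gspec, dspec, cfg, "h", 4)
        with pytest.raises(ValueError, match="trained"):
            synthesize_eeg(m, rng.random((3, 4)), [0, 1, 2])

    def test_output_shape_range_and_seed(self, quick_model, rng):
        s = rng.random((9, 4))
        y = rng.integers(0, 4, 9)
        out1 = synthesize_eeg(quick_model, s, y, seed=5)
        out2 = synthesize_eeg(quick_model, s, y, seed=5)
        out3 = synthesize_eeg(quick_model, s, y, seed=6)
        assert out1.shape == (9, 8)
        assert out1.min() >= 0.0 and out1.max() <= 1.0
        assert np.array_equal(out1, out2)
        assert not np.array_equal(out1, out3)

    def test_label_conditioning_separates_classes(self, scaled_mini):
        # on coupled data a trained generator produces distinct
        # class-conditional centroids
        model = train_hatl(scaled_mini, "cwgan-gp",
                           TrainConfig(epochs=25, batch_size=32, seed=3))
        s = scaled_mini.S_noneeg[:160]
        out_by_class = [synthesize_eeg(model, s, np.full(160, c), seed=1).mean(axis=0)
                        for c in range(4)]
        dists = [np.linalg.norm(out_by_class[i] - out_by_class[j])
                 for i in range(4) for j in range(i + 1, 4)]
        assert min(dists) > 0.02
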