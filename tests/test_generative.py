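"""The VAE-D2GAN networks and the terms of the four-player objective."""

import numpy as np
import pytest

from eegaug.generative import (GenerativeModel, LatentCode, NetworkSpec,
                               dense_spec, discriminate, encode, generate,
                               load_checkpoint, loss_d1, loss_d2,
                               loss_generator, loss_kl, loss_rec,
                               reparameterize, save_checkpoint,
                               total_objective)

from conftest import constant_discriminator_score


class TestReparameterize:
    def test_zero_gamma_returns_mu(self, rng):
        code = LatentCode(mu=rng.standard_normal((4, 8)).astype(np.float32),
                          log_sigma=rng.standard_normal((4, 8)).astype(np.float32))
        out = reparameterize(code, gamma=np.zeros((4, 8)))
        assert np.allclose(out.z, code.mu)

    def test_standard_code_returns_gamma(self, rng):
        gamma = rng.standard_normal((4, 8))
        code = LatentCode(mu=np.zeros((4, 8)), log_sigma=np.zeros((4, 8)))
        out = reparameterize(code, gamma=gamma)
        assert np.allclose(out.z, gamma, atol=1e-6)

    def test_hand_computed_example(self):
        """mu=(1,1), log_sigma=(ln2, ln2), gamma=(1,-1) -> z=(3,-1)."""
        code = LatentCode(mu=np.ones((1, 2)),
                          log_sigma=np.full((1, 2), np.log(2.0)))
        out = reparameterize(code, gamma=np.array([[1.0, -1.0]]))
        assert np.allclose(out.z, [[3.0, -1.0]], atol=1e-6)

    def test_seeded_draw_is_reproducible(self):
        code = LatentCode(mu=np.zeros((3, 5)), log_sigma=np.zeros((3, 5)))
        a = reparameterize(code, rng=np.random.default_rng(3)).z
        b = reparameterize(code, rng=np.random.default_rng(3)).z
        assert np.array_equal(a, b)


class TestNetworks:
    def test_encode_shapes_and_determinism(self, tiny_model, map_batch):
        c1 = encode(tiny_model, map_batch)
        c2 = encode(tiny_model, map_batch)
        assert c1.mu.shape == (6, 8) and c1.log_sigma.shape == (6, 8)
        assert c1.z is None
        assert np.array_equal(c1.mu, c2.mu) and np.array_equal(c1.log_sigma, c2.log_sigma)

    def test_zeroed_heads_give_zero_code(self, tiny_model, map_batch):
        for head in (tiny_model.encoder.head_mu, tiny_model.encoder.head_ls):
            head.params["W"][...] = 0.0
            head.params["b"][...] = 0.0
        code = encode(tiny_model, map_batch)
        assert np.all(code.mu == 0.0) and np.all(code.log_sigma == 0.0)

    def test_generate_shape_determinism_nonnegative(self, tiny_model, rng):
        z = rng.standard_normal((5, 8)).astype(np.float32)
        a = generate(tiny_model, z)
        b = generate(tiny_model, z)
        assert a.shape == (5, 5, 32, 32)
        assert np.array_equal(a, b)
        assert a.min() >= 0.0          # final ReLU

    def test_shape_round_trip(self, tiny_model, map_batch):
        code = reparameterize(encode(tiny_model, map_batch),
                              rng=np.random.default_rng(0))
        assert generate(tiny_model, code.z).shape == map_batch.shape

    def test_wrong_shapes_rejected(self, tiny_model, rng):
        with pytest.raises(ValueError):
            encode(tiny_model, rng.uniform(size=(2, 5, 16, 16)).astype(np.float32))
        with pytest.raises(ValueError):
            generate(tiny_model, rng.standard_normal((2, 9)).astype(np.float32))

    def test_discriminators_positive_and_independent(self, tiny_model, map_batch):
        s1 = discriminate(tiny_model, 1, map_batch)
        s2 = discriminate(tiny_model, 2, map_batch)
        assert (s1 > 0).all() and (s2 > 0).all()
        assert not np.allclose(s1, s2)     # independently initialized
        with pytest.raises(ValueError):
            discriminate(tiny_model, 3, map_batch)

    def test_perturbing_d1_leaves_d2_unchanged(self, tiny_model, map_batch):
        before = discriminate(tiny_model, 2, map_batch)
        for _, value, _ in tiny_model.d1.param_items():
            value += 0.5
        assert np.array_equal(discriminate(tiny_model, 2, map_batch), before)

    def test_zeroed_final_layer_scores_ln2(self, tiny_model, map_batch):
        s = constant_discriminator_score(tiny_model, 0.0)
        assert s == pytest.approx(np.log(2.0))
        assert np.allclose(discriminate(tiny_model, 1, map_batch), np.log(2.0),
                           atol=1e-6)

    def test_alpha_beta_range_enforced(self, tiny_spec):
        with pytest.raises(ValueError):
            GenerativeModel(spec=tiny_spec, alpha=0.0)
        with pytest.raises(ValueError):
            GenerativeModel(spec=tiny_spec, beta=1.5)


class TestLosses:
    def test_kl_zero_at_prior(self):
        code = LatentCode(mu=np.zeros((4, 8)), log_sigma=np.zeros((4, 8)))
        assert loss_kl(code) == pytest.approx(0.0)

    def test_kl_half_for_unit_mean_offset(self):
        mu = np.zeros((1, 8))
        mu[0, 0] = 1.0
        assert loss_kl(LatentCode(mu=mu, log_sigma=np.zeros((1, 8)))) == pytest.approx(0.5)

    def test_kl_nonnegative_on_random_codes(self, rng):
        for _ in range(20):
            code = LatentCode(mu=rng.standard_normal((3, 6)),
                              log_sigma=rng.standard_normal((3, 6)))
            assert loss_kl(code) >= 0.0

    def test_rec_zero_iff_identical_and_symmetric(self, map_batch, rng):
        assert loss_rec(map_batch, map_batch) == 0.0
        other = map_batch + rng.uniform(0.01, 0.1, map_batch.shape).astype(np.float32)
        assert loss_rec(map_batch, other) > 0.0
        assert loss_rec(map_batch, other) == pytest.approx(loss_rec(other, map_batch))

    def test_rec_hand_computed_value(self):
        x = np.zeros((1, 5, 32, 32))
        assert loss_rec(x, x + 0.1) == pytest.approx(0.1 ** 2 * 5 * 32 * 32)

    def test_rec_shape_mismatch_rejected(self, map_batch):
        with pytest.raises(ValueError):
            loss_rec(map_batch, map_batch[:, :, :16])

    def test_generator_loss_with_constant_discriminators(self, tiny_model, map_batch, rng):
        """Frozen constant score s on both Ds collapses L_G to -2s + 2 beta ln s."""
        s = constant_discriminator_score(tiny_model, 0.7)
        z = rng.standard_normal((6, 8)).astype(np.float32)
        zp = rng.standard_normal((6, 8)).astype(np.float32)
        lg = loss_generator(tiny_model, map_batch, z, zp)
        assert lg == pytest.approx(-2 * s + 2 * tiny_model.beta * np.log(s), rel=1e-5)

    def test_d1_d2_losses_with_constant_discriminators(self, tiny_model, map_batch):
        """Constant score s: L_D1 = alpha ln s - 2s and L_D2 = 2 beta ln s - s."""
        s = constant_discriminator_score(tiny_model, -0.3)
        a, b = tiny_model.alpha, tiny_model.beta
        l1 = loss_d1(tiny_model, map_batch, map_batch, map_batch)
        l2 = loss_d2(tiny_model, map_batch, map_batch, map_batch)
        assert l1 == pytest.approx(a * np.log(s) - 2 * s, rel=1e-5)
        assert l2 == pytest.approx(2 * b * np.log(s) - s, rel=1e-5)

    def test_total_objective_consistency(self, tiny_model, map_batch):
        report = total_objective(tiny_model, map_batch,
                                 rng=np.random.default_rng(5))
        assert report.l_vae == report.l_kl + report.l_rec
        assert np.isfinite(report.total)
        assert report.l_kl >= 0 and report.l_rec >= 0


class TestGradientSanity:
    def test_generator_step_does_not_increase_its_loss(self, tiny_model, rng):
        """One small descent step on G (frozen D1, D2, fixed z) must not
        increase L_G."""
        model = tiny_model
        z = rng.standard_normal((8, 8)).astype(np.float32)
        before = loss_generator(model, None, z[:4], z[4:])

        xg = model.generator.forward(z)
        s1 = discriminate(model, 1, xg)
        s2 = discriminate(model, 2, xg)
        n = 4
        d1 = model.d1.backward(np.full((8, 1), -1.0 / n, dtype=np.float32))
        d2 = model.d2.backward((model.beta / (n * np.maximum(s2, 1e-6)))[:, None]
                               .astype(np.float32))
        model.generator.zero_grad()
        model.generator.backward(d1 + d2)
        lr = 1e-4
        for _, value, grad in model.generator.param_items():
            value -= lr * grad
        after = loss_generator(model, None, z[:4], z[4:])
        assert after <= before + 1e-7


class TestCheckpoint:
    def test_round_trip_reproduces_outputs(self, tiny_model, tmp_path, rng):
        path = tmp_path / "model.npz"
        save_checkpoint(path, tiny_model)
        clone = load_checkpoint(path)
        z = rng.standard_normal((3, 8)).astype(np.float32)
        assert np.array_equal(generate(clone, z), generate(tiny_model, z))
        assert clone.alpha == tiny_model.alpha and clone.spec == tiny_model.spec

    def test_dense_spec_models_work(self, rng):
        model = GenerativeModel(spec=dense_spec(input_dim=2, latent_dim=4,
                                                hidden=(16, 16)), seed=1)
        pts = rng.standard_normal((10, 2)).astype(np.float32)
        code = encode(model, pts)
        assert code.mu.shape == (10, 4)
        out = generate(model, reparameterize(code, rng=rng).z)
        assert out.shape == (10, 2)
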