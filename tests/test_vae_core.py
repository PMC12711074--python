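"""Encoder/decoder contracts, reparameterization, β-VAE loss components
against independent oracles."""

import numpy as np
import pytest
from scipy.integrate import quad

from ccvae.vae_core import (LatentCode, VaeModel, beta_vae_loss, encode,
                            kl_divergence, load_checkpoint,
                            reconstruction_loss, reparameterize,
                            save_checkpoint)


@pytest.fixture(scope="module")
def small_model():
    return VaeModel(latent_dim=8, n_planes=5, image_size=32,
                    backbone="small", seed=0)


class TestEncode:
    def test_deterministic_and_correct_length(self, small_model, rng):
        x = rng.random((5, 32, 32))
        a, b = encode(small_model, x), encode(small_model, x)
        assert a.mu.shape == (1, 8)
        assert np.array_equal(a.mu, b.mu)
        assert np.array_equal(a.log_var, b.log_var)

    def test_batched_equals_per_item(self, small_model, rng):
        x = rng.random((3, 5, 32, 32))
        batch = encode(small_model, x)
        for i in range(3):
            single = encode(small_model, x[i])
            assert np.allclose(batch.mu[i], single.mu[0], atol=1e-9)

    def test_rotation_changes_code(self, small_model, rng):
        x = rng.random((5, 32, 32))
        rot = np.rot90(x, 2, axes=(1, 2)).copy()
        assert not np.allclose(encode(small_model, x).mu,
                               encode(small_model, rot).mu)

    def test_wrong_plane_count_rejected(self, small_model, rng):
        with pytest.raises(ValueError):
            encode(small_model, rng.random((3, 32, 32)))

    def test_non_finite_input_rejected(self, small_model):
        x = np.full((5, 32, 32), np.nan)
        with pytest.raises(ValueError):
            encode(small_model, x)


class TestRoundTripShapes:
    @pytest.mark.parametrize("backbone,size,planes", [
        ("small", 32, 5), ("small", 48, 3), ("resnet18", 32, 5),
        ("resnet18", 64, 2),
    ])
    def test_decode_matches_input_shape(self, backbone, size, planes, rng):
        model = VaeModel(latent_dim=6, n_planes=planes, image_size=size,
                         backbone=backbone, seed=1)
        x = rng.random((2, planes, size, size))
        code = encode(model, x)
        out = model.decode_np(code.mu)
        assert out.shape == x.shape

    def test_indivisible_image_size_rejected(self):
        with pytest.raises(ValueError):
            VaeModel(image_size=40, backbone="resnet18")


class TestReparameterize:
    def test_zero_variance_limit_returns_mu(self, rng):
        code = LatentCode(mu=np.ones((1, 4)), log_var=np.full((1, 4), -700.0))
        assert np.allclose(reparameterize(code, rng), 1.0)

    def test_same_seed_same_draw(self):
        code = LatentCode(mu=np.zeros((2, 3)), log_var=np.zeros((2, 3)))
        a = reparameterize(code, np.random.default_rng(4))
        b = reparameterize(code, np.random.default_rng(4))
        assert np.array_equal(a, b)

    def test_monte_carlo_mean_matches_mu(self):
        mu, log_var = 2.0, np.log(0.25)
        code = LatentCode(mu=np.full((10000, 1), mu),
                          log_var=np.full((10000, 1), log_var))
        z = reparameterize(code, np.random.default_rng(0))
        se = np.sqrt(np.exp(log_var) / 10000)
        assert abs(z.mean() - mu) < 4 * se


class TestReconstructionLoss:
    def test_perfect_reconstruction_is_zero(self, rng):
        x = rng.random((2, 5, 8, 8))
        assert reconstruction_loss(x, x.copy()) == 0.0

    def test_constant_offset_closed_form(self):
        x = np.zeros((1, 2, 4, 4))
        c = 0.7
        assert np.isclose(reconstruction_loss(x, x + c), c ** 2 / 2)

    def test_matches_two_loop_oracle(self, rng):
        x = rng.random((3, 2, 5, 5))
        y = rng.random((3, 2, 5, 5))
        total, n = 0.0, 0
        for a, b in zip(x.ravel(), y.ravel()):
            total += (a - b) ** 2
            n += 1
        assert np.isclose(reconstruction_loss(x, y), 0.5 * total / n,
                          rtol=1e-6)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            reconstruction_loss(rng.random((2, 3)), rng.random((3, 2)))


class TestKlDivergence:
    def test_prior_posterior_is_zero(self):
        assert kl_divergence((np.zeros((1, 6)), np.zeros((1, 6)))) == 0.0

    def test_unit_shift_closed_form(self):
        assert np.isclose(kl_divergence((np.ones((1, 1)), np.zeros((1, 1)))),
                          0.5)

    def test_matches_quadrature_oracle(self, rng):
        mu = rng.normal(size=3)
        log_var = rng.normal(scale=0.5, size=3)
        expected = 0.0
        for m, lv in zip(mu, log_var):
            s = np.sqrt(np.exp(lv))

            def integrand(t, m=m, s=s):
                log_q = -(t - m) ** 2 / (2 * s ** 2) - np.log(s) \
                    - 0.5 * np.log(2 * np.pi)
                log_p = -t ** 2 / 2 - 0.5 * np.log(2 * np.pi)
                return np.exp(log_q) * (log_q - log_p)

            expected += quad(integrand, -30, 30, limit=200)[0]
        got = kl_divergence((mu[None], log_var[None]))
        assert abs(got - expected) < 1e-4

    def test_nonnegative_property(self, rng):
        for _ in range(20):
            mu = rng.normal(size=(2, 5))
            lv = rng.normal(size=(2, 5))
            assert kl_divergence((mu, lv)) >= 0.0

    def test_non_finite_log_var_rejected(self):
        with pytest.raises(ValueError):
            kl_divergence((np.zeros((1, 2)), np.array([[np.inf, 0.0]])))


class TestBetaVaeLoss:
    def test_beta_zero_reduces_to_reconstruction(self, rng):
        x, y = rng.random((2, 1, 4, 4)), rng.random((2, 1, 4, 4))
        code = (rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))
        total, comps = beta_vae_loss(x, y, code, beta=0.0)
        assert total == comps["rec"] == reconstruction_loss(x, y)

    def test_perfect_model_is_zero(self, rng):
        x = rng.random((1, 1, 4, 4))
        code = (np.zeros((1, 2)), np.zeros((1, 2)))
        total, _ = beta_vae_loss(x, x.copy(), code, beta=1.0)
        assert total == 0.0

    def test_linear_in_beta(self, rng):
        x, y = rng.random((2, 1, 4, 4)), rng.random((2, 1, 4, 4))
        code = (rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))
        l0, _ = beta_vae_loss(x, y, code, beta=0.0)
        l2, _ = beta_vae_loss(x, y, code, beta=2.0)
        assert np.isclose(l2 - l0, 2.0 * kl_divergence(code), rtol=1e-12)


class TestCheckpoints:
    def test_round_trip_preserves_outputs(self, small_model, tmp_path, rng):
        x = rng.random((2, 5, 32, 32))
        small_model.intensity_mean = np.array([3.0, 4.0])
        path = str(tmp_path / "ckpt.npz")
        save_checkpoint(small_model, path, extras={"note": "test"})
        back = load_checkpoint(path)
        assert np.allclose(encode(back, x).mu, encode(small_model, x).mu)
        assert np.allclose(back.intensity_mean, [3.0, 4.0])

    def test_contract_mismatch_refused(self, small_model, tmp_path):
        path = str(tmp_path / "ckpt.npz")
        save_checkpoint(small_model, path)
        with pytest.raises(ValueError, match="contract"):
            load_checkpoint(path, expect={"latent_dim": 99})
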