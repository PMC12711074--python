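"""Auxiliary objectives: intensity regression, NT-Xent vs brute force,
composite-loss identities."""

import numpy as np
import pytest

from ccvae.autodiff import Tensor
from ccvae.nn import Linear
from ccvae.objectives import (LossWeights, PairSet, cc_vae_loss,
                              intensity_loss, nt_xent, predict_intensities)
from ccvae.vae_core import beta_vae_loss


def brute_force_nt_xent(Z, unordered_pairs, tau):
    """Independent double-loop evaluation of the batch contrastive loss."""
    Zn = Z / np.linalg.norm(Z, axis=1, keepdims=True)
    S = Zn @ Zn.T
    P = set()
    for i, j in unordered_pairs:
        P.add((i, j))
        P.add((j, i))
    total = 0.0
    for i, j in P:
        num = np.exp(S[i, j] / tau)
        den = sum(np.exp(S[i, k] / tau) for k in range(len(Z))
                  if k != i and (k, i) not in P)
        total += -np.log(num / den)
    return total / (2 * len(unordered_pairs))


class TestPairSet:
    def test_pairs_are_symmetric_and_counted_unordered(self):
        ps = PairSet([(0, 1), (2, 3)])
        assert (1, 0) in ps and (3, 2) in ps
        assert len(ps) == 2

    def test_terminal_frames_have_one_pair_interior_two(self):
        # one track with frames 0,1,2 fully present in the batch
        ps = PairSet.from_metadata(["a", "a", "a"], [0, 1, 2])
        assert ps.positives_of(0) == [1]      # first frame: one neighbour
        assert ps.positives_of(2) == [1]      # last frame: one neighbour
        assert ps.positives_of(1) == [0, 2]   # interior: both neighbours
        assert len(ps) == 2

    def test_self_pair_rejected(self):
        with pytest.raises(ValueError):
            PairSet([(1, 1)])


class TestPredictIntensities:
    def test_zero_weights_give_zero(self, rng):
        layer = Linear(4, 2, rng)
        layer.weight.data[:] = 0.0
        layer.bias.data[:] = 0.0
        assert np.allclose(predict_intensities(layer, rng.normal(size=(3, 4))),
                           0.0)

    def test_identity_map_on_2d(self, rng):
        layer = Linear(2, 2, rng)
        layer.weight.data = np.eye(2)
        layer.bias.data[:] = 0.0
        z = rng.normal(size=(4, 2))
        assert np.allclose(predict_intensities(layer, z), z)

    def test_gradient_wrt_weights_equals_z(self, rng):
        layer = Linear(3, 2, rng)
        z = rng.normal(size=3)
        out = predict_intensities(layer, Tensor(z))
        out.sum().backward()
        # d(sum of outputs)/dW = z broadcast over output columns
        assert np.allclose(layer.weight.grad, np.tile(z[:, None], (1, 2)))

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            predict_intensities(Linear(4, 2, rng), rng.normal(size=(2, 5)))


class TestIntensityLoss:
    def test_perfect_prediction_zero(self, rng):
        t = rng.random((4, 2))
        assert intensity_loss(t, t.copy()) == 0.0

    def test_closed_form_half(self):
        assert np.isclose(intensity_loss(np.array([[1.0, 0.0]]),
                                         np.array([[0.0, 0.0]])), 0.5)

    def test_matches_two_loop_oracle(self, rng):
        t, p = rng.random((6, 2)), rng.random((6, 2))
        acc = sum((a - b) ** 2 for a, b in zip(t.ravel(), p.ravel()))
        assert np.isclose(intensity_loss(t, p), acc / t.size, rtol=1e-6)

    def test_non_finite_targets_rejected(self, rng):
        with pytest.raises(ValueError):
            intensity_loss(np.array([[np.nan, 0.0]]), np.zeros((1, 2)))


class TestNtXent:
    def test_orthogonal_triplet_closed_form(self):
        Z = np.eye(3)
        assert nt_xent(Z, PairSet([(0, 1)]), temperature=1.0) == pytest.approx(0.0)

    def test_scale_invariance(self, rng):
        Z = rng.normal(size=(8, 6))
        ps = PairSet([(0, 1), (2, 3), (4, 5), (6, 7)])
        assert np.isclose(nt_xent(Z, ps, 0.7), nt_xent(5.0 * Z, ps, 0.7),
                          rtol=1e-12)

    @pytest.mark.parametrize("n,d,tau", [(6, 4, 0.7), (16, 8, 0.7),
                                         (64, 16, 0.5)])
    def test_matches_brute_force_oracle(self, n, d, tau, rng):
        Z = rng.normal(size=(n, d))
        pairs = [(i, i + 1) for i in range(0, n, 2)]
        assert np.isclose(nt_xent(Z, PairSet(pairs), tau),
                          brute_force_nt_xent(Z, pairs, tau), atol=1e-6)

    def test_differs_from_simclr_denominator(self, rng):
        """The denominator excludes the positive itself; including it (the
        original SimCLR convention) must give a different, larger value."""
        Z = rng.normal(size=(6, 4))
        pairs = [(0, 1), (2, 3), (4, 5)]
        ours = nt_xent(Z, PairSet(pairs), 0.7)
        Zn = Z / np.linalg.norm(Z, axis=1, keepdims=True)
        S = Zn @ Zn.T
        P = {(i, j) for i, j in pairs} | {(j, i) for i, j in pairs}
        simclr = np.mean([
            -np.log(np.exp(S[i, j] / 0.7)
                    / sum(np.exp(S[i, k] / 0.7) for k in range(6) if k != i))
            for i, j in P])
        assert simclr > ours

    def test_permutation_equivariance(self, rng):
        Z = rng.normal(size=(8, 5))
        pairs = [(0, 1), (2, 3), (4, 5), (6, 7)]
        perm = rng.permutation(8)
        inv = np.empty(8, dtype=int)
        inv[perm] = np.arange(8)
        permuted_pairs = [(inv[i], inv[j]) for i, j in pairs]
        assert np.isclose(nt_xent(Z, PairSet(pairs), 0.7),
                          nt_xent(Z[perm], PairSet(permuted_pairs), 0.7),
                          rtol=1e-12)

    def test_monotone_in_positive_similarity(self, rng):
        Z = rng.normal(size=(6, 4))
        ps = PairSet([(0, 1), (2, 3), (4, 5)])
        base = nt_xent(Z, ps, 0.7)
        Z2 = Z.copy()
        # move z1 toward z0, increasing their cosine similarity
        Z2[1] = 0.5 * Z2[1] + 0.5 * Z2[0] * (
            np.linalg.norm(Z2[1]) / np.linalg.norm(Z2[0]))
        assert nt_xent(Z2, ps, 0.7) < base

    def test_anchor_without_negatives_rejected(self):
        Z = np.random.default_rng(0).normal(size=(2, 3))
        with pytest.raises(ValueError, match="anchor"):
            nt_xent(Z, PairSet([(0, 1)]), 0.7)


class TestCompositeLoss:
    def _inputs(self, rng):
        x = rng.random((4, 1, 4, 4))
        x_hat = rng.random((4, 1, 4, 4))
        code = (rng.normal(size=(4, 3)), rng.normal(size=(4, 3)))
        t, p = rng.random((4, 2)), rng.random((4, 2))
        Z = rng.normal(size=(4, 3))
        ps = PairSet([(0, 1), (2, 3)])
        return x, x_hat, code, t, p, Z, ps

    def test_zero_lambdas_reduce_to_beta_vae(self, rng):
        x, x_hat, code, t, p, Z, ps = self._inputs(rng)
        w = LossWeights(beta=0.01, lambda1=0.0, lambda2=0.0)
        total, _ = cc_vae_loss(x, x_hat, code, t, p, Z, ps, w)
        expected, _ = beta_vae_loss(x, x_hat, code, beta=0.01)
        assert np.isclose(total, expected, rtol=1e-12)

    def test_all_perfect_gives_zero(self):
        x = np.random.default_rng(1).random((3, 1, 4, 4))
        code = (np.zeros((3, 2)), np.zeros((3, 2)))
        t = np.ones((3, 2))
        Z = np.eye(3)
        total, _ = cc_vae_loss(x, x.copy(), code, t, t.copy(), Z,
                               PairSet([(0, 1)]), LossWeights(temperature=1.0))
        assert total == pytest.approx(0.0)

    def test_breakdown_sums_to_total(self, rng):
        x, x_hat, code, t, p, Z, ps = self._inputs(rng)
        w = LossWeights()
        total, parts = cc_vae_loss(x, x_hat, code, t, p, Z, ps, w)
        recomposed = (parts["rec"] + w.beta * parts["kl"]
                      + w.lambda1 * parts["pip"] + w.lambda2 * parts["ntxent"])
        assert np.isclose(total, recomposed, atol=1e-9)
        assert np.isclose(parts["total"], total, atol=1e-9)


class TestLossWeights:
    def test_defaults_follow_published_values(self):
        w = LossWeights()
        assert (w.beta, w.lambda1, w.lambda2, w.temperature) == \
            (0.01, 1e4, 100.0, 0.7)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(beta=-0.1)
        with pytest.raises(ValueError):
            LossWeights(temperature=0.0)
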