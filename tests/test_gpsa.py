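"""Gaussian position-sensitive attention: closed forms, bias algebra, BCE."""

import numpy as np
import pytest

from hemaseg import gpsa
from hemaseg.errors import EmptyMaskError, ShapeMismatchError


def plain_attention_oracle(Q, K, V):
    """Brute-force scaled dot-product attention, written independently."""
    N, d = Q.shape
    out = np.zeros_like(V)
    for i in range(N):
        logits = np.array([Q[i] @ K[j] / np.sqrt(d) for j in range(N)])
        w = np.exp(logits - logits.max())
        w /= w.sum()
        out[i] = sum(w[j] * V[j] for j in range(N))
    return out


class TestTumorStats:
    def test_two_cell_mean_and_sigma(self):
        fm = np.array([[1.0, 3.0], [9.0, 9.0]])
        mask = np.array([[1, 1], [0, 0]])
        st = gpsa.tumor_stats(fm, mask)
        assert st.mu == 2.0
        assert st.sigma == pytest.approx(np.sqrt(1.0 + 1e-5), abs=1e-12)

    def test_constant_region_hits_stabilizer_floor(self):
        fm = np.full((4, 4), 2.5)
        mask = np.zeros((4, 4), dtype=int)
        mask[1:3, 1:3] = 1
        st = gpsa.tumor_stats(fm, mask)
        assert st.mu == 2.5
        assert st.sigma == pytest.approx(np.sqrt(1e-5), abs=1e-15)

    def test_empty_mask_directs_to_population_stats(self):
        with pytest.raises(EmptyMaskError, match="population"):
            gpsa.tumor_stats(np.ones((4, 4)), np.zeros((4, 4)))

    def test_fullres_mask_is_pooled_to_grid(self):
        fm = np.arange(16.0).reshape(4, 4)
        mask = np.zeros((16, 16), dtype=int)
        mask[0:4, 0:4] = 1  # covers exactly feature cell (0, 0)
        st = gpsa.tumor_stats(fm, mask)
        assert st.mu == 0.0


class TestGaussianMap:
    def test_zero_deviation_gives_one(self):
        st = gpsa.GaussianStats(mu=0.5, sigma=1.0)
        G = gpsa.gaussian_map(np.full((3, 3), 0.5), st, k=1.0)
        np.testing.assert_allclose(G, 1.0)

    def test_one_sigma_deviation_closed_form(self):
        st = gpsa.GaussianStats(mu=0.0, sigma=10.0)  # sigma^2 >> epsilon
        G = gpsa.gaussian_map(np.array([[10.0]]), st, k=1.0)
        assert G[0, 0] == pytest.approx(np.exp(-0.5), abs=1e-6)

    def test_wide_scale_limit(self):
        st = gpsa.GaussianStats(mu=0.0, sigma=1.0)
        G = gpsa.gaussian_map(np.array([[3.0]]), st, k=100.0)
        assert G[0, 0] == pytest.approx(1.0, abs=1e-3)

    def test_multiscale_closed_form(self):
        st = gpsa.GaussianStats(mu=0.0, sigma=10.0)
        G = gpsa.multiscale_gaussian(np.array([[10.0]]), st)
        expected = (np.exp(-2.0) + np.exp(-0.5) + np.exp(-0.125)) / 3.0
        assert G[0, 0] == pytest.approx(expected, abs=1e-6)

    def test_multiscale_bounded_by_scale_extremes(self, rng):
        st = gpsa.GaussianStats(mu=0.2, sigma=1.3)
        fm = rng.normal(size=(6, 6))
        per_scale = np.stack([gpsa.gaussian_map(fm, st, k) for k in st.scales])
        G = gpsa.multiscale_gaussian(fm, st)
        assert np.all(G >= per_scale.min(axis=0) - 1e-12)
        assert np.all(G <= per_scale.max(axis=0) + 1e-12)

    def test_affine_standardization_invariance(self, rng):
        """G depends on features only through (I - mu)/sigma, up to the
        epsilon stabilizer."""
        fm = rng.normal(0.0, 1.5, size=(8, 8))
        mask = np.zeros((8, 8), dtype=int)
        mask[2:6, 2:6] = 1
        a, b = 2.5, -1.0
        G1 = gpsa.multiscale_gaussian(fm, gpsa.tumor_stats(fm, mask))
        G2 = gpsa.multiscale_gaussian(a * fm + b, gpsa.tumor_stats(a * fm + b, mask))
        assert np.abs(G1 - G2).max() < 1e-3


class TestBias:
    def test_uniform_map_gives_all_ones_matrix(self):
        bias = gpsa.build_bias(np.ones((2, 2)))
        np.testing.assert_array_equal(bias.B, np.ones((4, 4)))

    def test_hand_outer_product(self):
        bias = gpsa.build_bias(np.array([[1.0, 0.5]]))
        np.testing.assert_allclose(bias.B, [[1.0, 0.5], [0.5, 0.25]])

    def test_rank_one_spectrum(self, rng):
        G = rng.uniform(0.1, 1.0, size=(3, 3))
        bias = gpsa.build_bias(G)
        evals = np.sort(np.linalg.eigvalsh(bias.B))
        np.testing.assert_allclose(evals[-1], bias.g @ bias.g, rtol=1e-10)
        np.testing.assert_allclose(evals[:-1], 0.0, atol=1e-10)
        np.testing.assert_array_equal(bias.B, bias.B.T)

    def test_permutation_equivariance(self, rng):
        G = rng.uniform(0.1, 1.0, size=(2, 3))
        perm = rng.permutation(6)
        B = gpsa.build_bias(G).B
        B_perm = gpsa.build_bias(G.reshape(-1)[perm].reshape(2, 3)).B
        np.testing.assert_allclose(B_perm, B[np.ix_(perm, perm)])

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            gpsa.build_bias(np.array([[1.0, np.inf]]))


class TestBiasedAttention:
    @pytest.mark.parametrize("n_tokens", [4, 6, 8])
    def test_zero_lambda_equals_plain_oracle(self, n_tokens, rng):
        Q, K, V = rng.normal(size=(3, n_tokens, 5))
        bias = gpsa.build_bias(rng.uniform(0.1, 1.0, size=(n_tokens,)), lambda_bias=0.0)
        out = gpsa.biased_attention(Q, K, V, bias)
        np.testing.assert_allclose(out, plain_attention_oracle(Q, K, V), atol=1e-6)

    def test_two_token_hand_computation(self):
        Q = K = np.array([[1.0], [0.0]])
        V = np.eye(2)
        bias = gpsa.AttentionBias(g=np.ones(2), B=np.ones((2, 2)), lambda_bias=0.5)
        out = gpsa.biased_attention(Q, K, V, bias)
        # A = [[1.5, 0.5], [0.5, 0.5]]
        np.testing.assert_allclose(out[0], [0.7311, 0.2689], atol=1e-4)
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-6)

    @pytest.mark.parametrize("lam", [0.1, 0.5, 3.0])
    def test_uniform_g_is_softmax_shift_invariant(self, lam, rng):
        Q, K, V = rng.normal(size=(3, 5, 4))
        bias = gpsa.build_bias(np.full(5, 0.7), lambda_bias=lam)
        np.testing.assert_allclose(gpsa.biased_attention(Q, K, V, bias),
                                   gpsa.biased_attention(Q, K, V, None), atol=1e-10)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ShapeMismatchError):
            gpsa.biased_attention(rng.normal(size=(4, 3)), rng.normal(size=(5, 3)),
                                  rng.normal(size=(4, 2)))
        with pytest.raises(ShapeMismatchError):
            gpsa.biased_attention(rng.normal(size=(4, 3)), rng.normal(size=(4, 3)),
                                  rng.normal(size=(4, 2)),
                                  gpsa.build_bias(np.ones(3)))


class TestSupervision:
    def test_target_extremes(self):
        assert gpsa.attention_supervision_target(np.ones((8, 8)), (2, 2)).tolist() \
            == [1.0] * 4
        assert gpsa.attention_supervision_target(np.zeros((8, 8)), (2, 2)).tolist() \
            == [0.0] * 4

    def test_corner_tumor_target(self):
        mask = np.zeros((4, 4))
        mask[:2, :2] = 1
        np.testing.assert_array_equal(
            gpsa.attention_supervision_target(mask, (2, 2)), [1.0, 0.0, 0.0, 0.0])

    def test_grid_larger_than_mask_rejected(self):
        with pytest.raises(ShapeMismatchError):
            gpsa.attention_supervision_target(np.ones((2, 2)), (4, 4))

    def test_uniform_attention_hand_bce(self):
        N = 4
        A = np.zeros((N, N))  # softmax rows are uniform: p = 1/4
        target = np.array([1.0, 1.0, 0.0, 0.0])
        p = 0.25
        expected = -(2 * np.log(p) + 2 * np.log(1 - p)) / 4
        assert gpsa.attention_supervision_loss(A, target) == pytest.approx(expected, 1e-10)

    def test_permutation_equivariance(self, rng):
        A = rng.normal(size=(5, 5))
        target = (rng.random(5) > 0.5).astype(float)
        perm = rng.permutation(5)
        assert gpsa.attention_supervision_loss(A, target) == pytest.approx(
            gpsa.attention_supervision_loss(A[np.ix_(perm, perm)], target[perm]), 1e-12)

    def test_loss_decreases_as_attention_concentrates_on_tumor(self):
        target = np.array([1.0, 0.0, 0.0, 0.0])
        losses = []
        for sharp in (0.0, 1.0, 3.0, 6.0):
            A = np.tile(np.array([sharp, 0.0, 0.0, 0.0]), (4, 1))
            losses.append(gpsa.attention_supervision_loss(A, target))
        assert all(a > b for a, b in zip(losses, losses[1:]))


class TestPopulationStats:
    def test_single_case_identity(self):
        st = gpsa.GaussianStats(1.5, 2.0)
        pooled = gpsa.population_stats([st])
        assert pooled.mu == 1.5 and pooled.sigma == 2.0

    def test_plain_averages(self):
        stats = [gpsa.GaussianStats(1.0, 1.0), gpsa.GaussianStats(3.0, 2.0),
                 gpsa.GaussianStats(2.0, 3.0)]
        pooled = gpsa.population_stats(stats)
        assert pooled.mu == 2.0 and pooled.sigma == 2.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gpsa.population_stats([])
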