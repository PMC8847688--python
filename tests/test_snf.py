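import itertools

import numpy as np
import pytest

from graphfuse.snf import (
    affinity_matrix,
    between_within_ratio,
    diffusion_step,
    fuse_views,
    snf_fuse,
    transition_kernels,
)

# hand-computed scaled-exponential kernel for the 4-point example
# (pairs (0,0),(0,1) and (5,5),(5,6); mu=0.5, K=1):
# rho(0,1)=1, eps=(1+1+1)/3=1, W=exp(-1/0.5)=exp(-2)
W01 = np.exp(-2.0)
# rho^2(0,2)=50, eps=(1+1+sqrt(50))/3, W=exp(-50/(0.5*eps))
W02 = np.exp(-50.0 / (0.5 * (2 + np.sqrt(50.0)) / 3))
W03 = np.exp(-61.0 / (0.5 * (2 + np.sqrt(61.0)) / 3))
W12 = np.exp(-41.0 / (0.5 * (2 + np.sqrt(41.0)) / 3))


class TestAffinityMatrix:
    def test_identical_samples_full_similarity(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [3.0, 4.0]])
        with pytest.warns(UserWarning, match="identical"):
            aff = affinity_matrix(X, mu=0.5, K=1)
        assert aff.W[0, 1] == pytest.approx(1.0)

    def test_unit_diagonal(self):
        rng = np.random.default_rng(0)
        aff = affinity_matrix(rng.normal(size=(10, 4)), K=3)
        np.testing.assert_allclose(np.diagonal(aff.W), 1.0)

    def test_four_point_hand_oracle(self, four_points):
        aff = affinity_matrix(four_points, mu=0.5, K=1)
        expected = np.array(
            [
                [1.0, W01, W02, W03],
                [W01, 1.0, W12, W02],
                [W02, W12, 1.0, W01],
                [W03, W02, W01, 1.0],
            ]
        )
        np.testing.assert_allclose(aff.W, expected, rtol=1e-12)

    def test_symmetry_invariant(self):
        rng = np.random.default_rng(1)
        aff = affinity_matrix(rng.normal(size=(25, 6)), K=5)
        np.testing.assert_allclose(aff.W, aff.W.T, atol=1e-15)

    def test_precomputed_distances(self, four_points):
        from scipy.spatial.distance import cdist

        direct = affinity_matrix(four_points, mu=0.5, K=1)
        pre = affinity_matrix(cdist(four_points, four_points), mu=0.5, K=1,
                              precomputed_distances=True)
        np.testing.assert_allclose(direct.W, pre.W)

    def test_invalid_k(self, four_points):
        with pytest.raises(ValueError, match="K must be"):
            affinity_matrix(four_points, K=4)


class TestTransitionKernels:
    def test_equal_offdiagonal_forces_quarters(self):
        # n=3, all off-diagonal W equal -> P off-diagonals 1/4, diagonal 1/2
        from graphfuse.snf import AffinityMatrix

        W = np.full((3, 3), 0.3)
        np.fill_diagonal(W, 1.0)
        k = transition_kernels(AffinityMatrix(W=W, mu=0.5, K=1))
        expected = np.full((3, 3), 0.25)
        np.fill_diagonal(expected, 0.5)
        np.testing.assert_allclose(k.P, expected)

    def test_rows_sum_to_one_random(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = rng.integers(4, 12)
            X = rng.normal(size=(n, 3))
            k = transition_kernels(affinity_matrix(X, K=min(3, n - 1)))
            np.testing.assert_allclose(k.P.sum(axis=1), 1.0, atol=1e-10)
            np.testing.assert_allclose(np.diagonal(k.P), 0.5, atol=1e-10)
            np.testing.assert_allclose(k.S.sum(axis=1), 1.0, atol=1e-10)

    def test_k1_sparse_kernel_single_unit_entry(self, four_points):
        k = transition_kernels(affinity_matrix(four_points, mu=0.5, K=1))
        assert ((k.S > 0).sum(axis=1) == 1).all()
        np.testing.assert_allclose(k.S[k.S > 0], 1.0)
        # nearest neighbors: 0<->1, 2<->3
        np.testing.assert_array_equal(np.argmax(k.S, axis=1), [1, 0, 3, 2])

    def test_sparse_support_is_k_neighbors(self):
        rng = np.random.default_rng(3)
        k = transition_kernels(affinity_matrix(rng.normal(size=(15, 4)), K=4))
        assert ((k.S > 0).sum(axis=1) == 4).all()
        for i, nbr in enumerate(k.neighbors):
            assert len(nbr) == 4 and i not in nbr


class TestSnfFuse:
    def _kernels(self, seed=4, n=20, m=2):
        rng = np.random.default_rng(seed)
        return [
            transition_kernels(affinity_matrix(rng.normal(size=(n, 5)), K=4))
            for _ in range(m)
        ]

    def test_single_view_is_identity_operation(self):
        (k,) = self._kernels(m=1)
        fused = snf_fuse([k])
        np.testing.assert_array_equal(fused.P_fused, k.P)

    def test_one_step_equals_brute_force_triple_product(self, four_points):
        # independent oracle: direct matrix multiplication of S P S^T
        k1 = transition_kernels(affinity_matrix(four_points, mu=0.5, K=1))
        k2 = transition_kernels(affinity_matrix(four_points * 1.5 + 0.3, mu=0.5, K=1))
        stepped = diffusion_step([k1.P, k2.P], [k1.S, k2.S])
        np.testing.assert_allclose(stepped[0], k1.S @ k2.P @ k1.S.T, atol=1e-12)
        np.testing.assert_allclose(stepped[1], k2.S @ k1.P @ k2.S.T, atol=1e-12)

    def test_general_form_reduces_to_two_view_scheme(self):
        # the m-view update with m=2 must equal the alternating two-view
        # update, computed here independently by explicit products
        ks = self._kernels(seed=5)
        Ps = [k.P for k in ks]
        Ss = [k.S for k in ks]
        general = diffusion_step(Ps, Ss)
        np.testing.assert_allclose(general[0], Ss[0] @ Ps[1] @ Ss[0].T, atol=1e-15)
        np.testing.assert_allclose(general[1], Ss[1] @ Ps[0] @ Ss[1].T, atol=1e-15)

    def test_view_order_permutation_invariance(self):
        ks = self._kernels(seed=6, m=3)
        ref = snf_fuse(ks, t_max=10).P_fused
        for perm in itertools.permutations(range(3)):
            out = snf_fuse([ks[i] for i in perm], t_max=10).P_fused
            np.testing.assert_allclose(out, ref, atol=1e-8)

    def test_fused_symmetric_and_nearly_row_stochastic(self):
        fused = snf_fuse(self._kernels(seed=7), t_max=10)
        M = fused.P_fused
        np.testing.assert_array_equal(M, M.T)
        np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=0.35)

    def test_mismatched_n_rejected(self):
        k1 = self._kernels(seed=8, n=10, m=1)[0]
        k2 = self._kernels(seed=8, n=12, m=1)[0]
        with pytest.raises(ValueError, match="share"):
            snf_fuse([k1, k2])

    def test_block_structure_preserved_identical_views(self):
        # two identical informative views: within-block similarity stays
        # above between-block at every iteration
        rng = np.random.default_rng(9)
        y = np.repeat([0, 1], 15)
        X = rng.normal(size=(30, 8)) + 3.0 * y[:, None]
        k = transition_kernels(affinity_matrix(X, K=5))
        for t in (1, 3, 10):
            fused = snf_fuse(
                [k, transition_kernels(affinity_matrix(X, K=5))], t_max=t
            ).P_fused
            assert between_within_ratio(fused, y) < 1.0

    def test_change_norm_decreases_after_burn_in(self):
        fused = snf_fuse(self._kernels(seed=10), t_max=15, tol=0.0)
        deltas = fused.change_norms[2:]
        assert all(b <= a * 1.05 for a, b in zip(deltas, deltas[1:]))


def test_noise_suppression_on_realized_network():
    """Fusing an informative view with pure noise hurts the realized
    network's cluster separation less than naive kernel averaging."""
    wins = 0
    for seed in range(5):
        rng = np.random.default_rng(seed)
        n = 100
        y = np.repeat([0, 1], n // 2)
        shift = rng.normal(size=40)
        shift *= 3.0 / np.linalg.norm(shift) * np.sqrt(40)
        X_info = rng.normal(size=(n, 40)) + y[:, None] * shift
        X_noise = rng.normal(size=(n, 40))
        a1 = affinity_matrix(X_info)
        a2 = affinity_matrix(X_noise)
        k1, k2 = transition_kernels(a1), transition_kernels(a2)
        fused = snf_fuse([k1, k2]).P_fused
        naive = (k1.P + k2.P) / 2
        K = a1.K
        if between_within_ratio(fused, y, top_k=K) <= between_within_ratio(
            naive, y, top_k=K
        ):
            wins += 1
    assert wins == 5


def test_fuse_views_end_to_end(small_dataset):
    ds, truth = small_dataset
    fused = fuse_views([l.matrix for l in ds.layers], sample_ids=ds.sample_ids)
    y = ds.label_array()
    assert fused.P_fused.shape == (ds.n_samples, ds.n_samples)
    assert between_within_ratio(fused.P_fused, y, top_k=10) < 0.5
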