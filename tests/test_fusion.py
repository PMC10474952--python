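import numpy as np
import pytest

from fusedrp.entities import EntityIndex, SimilarityView, SNFParams
from fusedrp.fusion import (
    default_k,
    fill_sparse_view,
    fuse_all_drug_views,
    fuse_smiles_views,
    snf_fuse,
)


# ---------------------------------------------------------------------------
# independent dense-loop SNF oracle (explicit loops, no vectorization shared
# with the implementation)
# ---------------------------------------------------------------------------

def oracle_full_kernel(W):
    n = len(W)
    P = [[0.0] * n for _ in range(n)]
    for i in range(n):
        row_sum = sum(W[i][j] for j in range(n) if j != i)
        for j in range(n):
            if i == j:
                P[i][j] = 0.5
            elif row_sum > 0:
                P[i][j] = W[i][j] / (2.0 * row_sum)
    return P


def oracle_knn_kernel(W, k):
    n = len(W)
    S = [[0.0] * n for _ in range(n)]
    for i in range(n):
        neighbours = sorted((j for j in range(n) if j != i),
                            key=lambda j: -W[i][j])[:k]
        total = sum(W[i][j] for j in neighbours)
        if total > 0:
            for j in neighbours:
                S[i][j] = W[i][j] / total
    return S


def oracle_snf(views, k, t):
    n = len(views[0])
    P = [oracle_full_kernel(W) for W in views]
    S = [oracle_knn_kernel(W, k) for W in views]
    V = len(views)
    for _ in range(t):
        new_P = []
        for v in range(V):
            mean_other = [[sum(P[u][i][j] for u in range(V) if u != v) / (V - 1)
                           for j in range(n)] for i in range(n)]
            # Q = S_v * mean_other * S_v^T
            tmp = [[sum(S[v][i][a] * mean_other[a][j] for a in range(n))
                    for j in range(n)] for i in range(n)]
            Q = [[sum(tmp[i][a] * S[v][j][a] for a in range(n))
                  for j in range(n)] for i in range(n)]
            Qs = [[(Q[i][j] + Q[j][i]) / 2.0 for j in range(n)]
                  for i in range(n)]
            new_P.append(oracle_full_kernel(Qs))
        P = new_P
    fused = [[sum(P[v][i][j] for v in range(V)) / V for j in range(n)]
             for i in range(n)]
    return np.array([[(fused[i][j] + fused[j][i]) / 2.0 for j in range(n)]
                     for i in range(n)])


def _views(matrices, ids=None):
    n = matrices[0].shape[0]
    index = EntityIndex(ids or tuple(f"d{i}" for i in range(n)), "drug")
    return [SimilarityView(index=index, view_name=f"v{i}", S=M)
            for i, M in enumerate(matrices)]


def _random_similarity(rng, n):
    X = rng.random((n, 3))
    D = np.abs(X[:, None, :] - X[None, :, :]).max(axis=2)
    S = 1.0 - D / max(D.max(), 1e-12)
    S = (S + S.T) / 2
    np.fill_diagonal(S, 1.0)
    return S


class TestSNFOracle:
    @pytest.mark.parametrize("k,t", [(3, 10), (5, 20)])
    def test_matches_dense_loop_oracle(self, rng, k, t):
        mats = [_random_similarity(rng, 8) for _ in range(3)]
        fused = snf_fuse(_views(mats), k=k, t=t)
        expected = oracle_snf([M.tolist() for M in mats], k=k, t=t)
        np.testing.assert_allclose(fused.S, expected, atol=1e-8)

    def test_identical_views(self, rng):
        M = _random_similarity(rng, 5)
        fused = snf_fuse(_views([M.copy(), M.copy(), M.copy()]), k=3, t=5)
        expected = oracle_snf([M.tolist()] * 3, k=3, t=5)
        np.testing.assert_allclose(fused.S, expected, atol=1e-10)

    def test_t_zero_is_mean_of_full_kernels(self, rng):
        mats = [_random_similarity(rng, 6) for _ in range(2)]
        fused = snf_fuse(_views(mats), k=3, t=0)
        expected = np.mean([oracle_full_kernel(M.tolist()) for M in mats],
                           axis=0)
        expected = (expected + expected.T) / 2.0  # output contract symmetrizes
        np.testing.assert_allclose(fused.S, expected, atol=1e-12)

    def test_block_structure_preserved(self, rng):
        # two views sharing a 2-block structure
        block = np.full((3, 3), 0.9)
        S = np.full((6, 6), 0.05)
        S[:3, :3] = block
        S[3:, 3:] = block
        np.fill_diagonal(S, 1.0)
        noisy = np.clip(S + rng.normal(scale=0.01, size=S.shape), 0, 1)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 1.0)
        fused = snf_fuse(_views([S, noisy]), k=2, t=10).S
        within = np.concatenate([fused[:3, :3][np.triu_indices(3, 1)],
                                 fused[3:, 3:][np.triu_indices(3, 1)]])
        between = fused[:3, 3:].ravel()
        assert within.mean() > between.mean()

    def test_symmetry_and_nonnegativity(self, rng):
        mats = [_random_similarity(rng, 7) for _ in range(4)]
        fused = snf_fuse(_views(mats), k=3, t=15).S
        assert np.abs(fused - fused.T).max() <= 1e-12
        assert fused.min() >= 0

    def test_permutation_equivariance(self, rng):
        mats = [_random_similarity(rng, 6) for _ in range(3)]
        perm = rng.permutation(6)
        fused = snf_fuse(_views(mats), k=3, t=8).S
        mats_p = [M[np.ix_(perm, perm)] for M in mats]
        fused_p = snf_fuse(_views(mats_p), k=3, t=8).S
        np.testing.assert_allclose(fused_p, fused[np.ix_(perm, perm)],
                                   atol=1e-10)

    def test_k_too_large_rejected(self, rng):
        mats = [_random_similarity(rng, 5) for _ in range(2)]
        with pytest.raises(ValueError, match="k must satisfy"):
            snf_fuse(_views(mats), k=5, t=3)

    def test_asymmetric_input_rejected(self):
        index = EntityIndex(("a", "b", "c"), "drug")
        M = np.eye(3)
        views = [SimilarityView(index=index, view_name="v", S=M.copy())
                 for _ in range(2)]
        views[0].S[0, 1] = 0.5  # break symmetry after validation
        with pytest.raises(ValueError, match="not symmetric"):
            snf_fuse(views, k=2, t=3)

    def test_default_k(self):
        assert default_k(30) == 3
        assert default_k(580) == 58
        assert default_k(4) == 3


class TestFillSparseView:
    def _view_with_zero_rows(self, S, mask):
        n = S.shape[0]
        index = EntityIndex(tuple(f"d{i}" for i in range(n)), "drug")
        return SimilarityView(index=index, view_name="target", S=S,
                              zero_row_mask=np.asarray(mask))

    def _fused(self, F, index):
        from fusedrp.entities import FusedSimilarity
        return FusedSimilarity(index=index, S=F, source_views=("ECFP",),
                               snf_params=SNFParams(k=2, t=5))

    def test_no_zero_rows_pass_through(self, rng):
        S = _random_similarity(rng, 4)
        view = self._view_with_zero_rows(S, [False] * 4)
        F = _random_similarity(rng, 4)
        cv = fill_sparse_view(view, self._fused(F, view.index))
        np.testing.assert_array_equal(cv.S, S)
        assert cv.filled_entities == frozenset()

    def test_fill_row_and_column(self):
        S = np.eye(3)
        S[0, 2] = S[2, 0] = 0.4
        view = self._view_with_zero_rows(S, [False, True, False])
        F = np.array([[1.0, 0.3, 0.2],
                      [0.3, 1.0, 0.7],
                      [0.2, 0.7, 1.0]])
        cv = fill_sparse_view(view, self._fused(F, view.index))
        np.testing.assert_allclose(cv.S[1, :], [0.3, 1.0, 0.7])
        np.testing.assert_allclose(cv.S[:, 1], [0.3, 1.0, 0.7])
        assert cv.filled_entities == frozenset({"d1"})

    def test_untouched_complement_bit_identical(self, rng):
        S = _random_similarity(rng, 6)
        mask = [False, True, False, False, True, False]
        view = self._view_with_zero_rows(S, mask)
        F = _random_similarity(rng, 6)
        cv = fill_sparse_view(view, self._fused(F, view.index))
        keep = np.flatnonzero(~np.asarray(mask))
        assert np.array_equal(cv.S[np.ix_(keep, keep)],
                              S[np.ix_(keep, keep)])

    def test_symmetry_after_filling_two_entities(self, rng):
        S = _random_similarity(rng, 5)
        view = self._view_with_zero_rows(S, [True, False, False, True, False])
        F = _random_similarity(rng, 5)
        cv = fill_sparse_view(view, self._fused(F, view.index))
        np.testing.assert_array_equal(cv.S, cv.S.T)
        np.testing.assert_array_equal(np.diag(cv.S), np.ones(5))


class TestFuseHelpers:
    def test_fuse_smiles_requires_six_fingerprint_views(self, rng):
        mats = [_random_similarity(rng, 6) for _ in range(6)]
        index = EntityIndex(tuple(f"d{i}" for i in range(6)), "drug")
        names = ("ECFP", "PSFP", "DFP", "RDKFP", "ESPFP", "ERGFP")
        views = [SimilarityView(index=index, view_name=nm, S=M)
                 for nm, M in zip(names, mats)]
        fused = fuse_smiles_views(views, k=3, t=5)
        assert sorted(fused.source_views) == sorted(names)
        with pytest.raises(ValueError, match="fingerprint views"):
            fuse_smiles_views(views[:5], k=3, t=5)

    def test_fuse_all_requires_twelve(self, rng):
        mats = [_random_similarity(rng, 6) for _ in range(11)]
        with pytest.raises(ValueError, match="12"):
            fuse_all_drug_views(_views(mats), k=3, t=5)
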