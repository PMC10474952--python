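"""Similarity network fusion (SNF) and completion of sparse views.

SNF (Wang et al.'s cross-diffusion scheme) merges several entity x entity
similarity networks into one.  Each view is normalized into a full kernel
P (diagonal 1/2, off-diagonal rows summing to 1/2) and a sparse K-nearest
neighbour kernel S (row-stochastic over the K strongest neighbours);
T rounds of P_v <- S_v . mean(P_u, u != v) . S_v^T with symmetrization and
re-normalization diffuse information across views, and the fused network is
the mean of the final kernels.

Completion: association-derived similarity views have undefined rows for
entities absent from the source database.  Those rows and columns are
replaced by the corresponding rows of the fused fingerprint (SMILES-derived)
network, which is always dense.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .entities import (
    CompletedView,
    DRUG_FINGERPRINT_VIEWS,
    FusedSimilarity,
    SimilarityView,
    SNFParams,
)

__all__ = [
    "snf_fuse",
    "fuse_smiles_views",
    "fill_sparse_view",
    "fuse_all_drug_views",
    "affinity_from_distance",
    "default_k",
]

#: views completed from the fused fingerprint network (sparse-source views)
COMPLETABLE_VIEWS = ("combined", "target", "disease", "miRNA", "ADR")


def default_k(n: int) -> int:
    """Default SNF neighbourhood size: max(3, round(n/10)), capped at n-1."""
    return min(max(3, round(n / 10)), n - 1)


def affinity_from_distance(D: np.ndarray, k: int, mu: float = 0.5) -> np.ndarray:
    """Scaled-exponential-kernel affinity from a distance matrix.

    W_ij = exp(-d_ij^2 / (mu * eps_ij)) with eps_ij the mean of the two
    rows' mean-K-nearest distances and d_ij itself.  Provided for users who
    start from distances; the fusion entry points below consume similarity
    views directly.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("distance matrix must be square")
    sorted_rows = np.sort(D, axis=1)
    # mean distance to the k nearest other entities (column 0 is self)
    t = sorted_rows[:, 1 : k + 1].mean(axis=1)
    eps = (t[:, None] + t[None, :] + D) / 3.0
    eps = np.maximum(eps, 1e-12)
    W = np.exp(-(D**2) / (mu * eps))
    return (W + W.T) / 2.0


def _full_kernel(W: np.ndarray) -> np.ndarray:
    """P normalization: diag 1/2, off-diagonal rows summing to 1/2."""
    n = W.shape[0]
    off = W.copy()
    np.fill_diagonal(off, 0.0)
    row = off.sum(axis=1)
    P = np.zeros_like(W)
    nz = row > 0
    P[nz] = off[nz] / (2.0 * row[nz, None])
    np.fill_diagonal(P, 0.5)
    return P


def _knn_kernel(W: np.ndarray, k: int) -> np.ndarray:
    """Sparse kernel: row-stochastic over each row's K strongest neighbours."""
    n = W.shape[0]
    off = W.copy()
    np.fill_diagonal(off, -np.inf)
    # indices of the K largest entries per row (excluding self)
    idx = np.argsort(-off, axis=1, kind="stable")[:, :k]
    S = np.zeros_like(W)
    rows = np.repeat(np.arange(n), k)
    S[rows, idx.ravel()] = W[rows, idx.ravel()]
    norm = S.sum(axis=1)
    nz = norm > 0
    S[nz] /= norm[nz, None]
    return S


def snf_fuse(
    views: Sequence[SimilarityView],
    k: int | None = None,
    t: int = 20,
    mu: float = 0.5,
) -> FusedSimilarity:
    """Fuse >=2 similarity views of the same entities by cross-diffusion.

    With t=0 the output is simply the mean of the full kernels.  The input
    similarities are used directly as affinities (they are already [0,1]
    with unit diagonal); ``mu`` is recorded in the output's parameters and
    only enters when affinities are built from distances upstream.
    """
    if len(views) < 2:
        raise ValueError("SNF needs at least two views")
    index = views[0].index
    n = len(index)
    if n < 3:
        raise ValueError("SNF needs at least 3 entities")
    for v in views:
        if v.index.ids != index.ids:
            raise ValueError("all views must share one EntityIndex")
        if not np.array_equal(v.S, v.S.T):
            raise ValueError(f"view {v.view_name!r} is not symmetric")
    if k is None:
        k = default_k(n)
    if not (1 <= k <= n - 1):
        raise ValueError(f"k must satisfy 1 <= k <= n-1, got k={k}, n={n}")

    P = [_full_kernel(v.S) for v in views]
    S = [_knn_kernel(v.S, k) for v in views]
    V = len(views)
    for _ in range(t):
        new_P = []
        for v in range(V):
            others = [P[u] for u in range(V) if u != v]
            mean_other = np.mean(others, axis=0)
            Q = S[v] @ mean_other @ S[v].T
            Q = (Q + Q.T) / 2.0
            new_P.append(_full_kernel(Q))
        P = new_P
    fused = np.mean(P, axis=0)
    fused = (fused + fused.T) / 2.0
    return FusedSimilarity(
        index=index,
        S=fused,
        source_views=tuple(v.view_name for v in views),
        snf_params=SNFParams(k=k, t=t, mu=mu),
    )


def fuse_smiles_views(
    views: Sequence[SimilarityView],
    k: int | None = None,
    t: int = 20,
    mu: float = 0.5,
) -> FusedSimilarity:
    """Fuse exactly the six fingerprint similarity views."""
    names = sorted(v.view_name for v in views)
    if names != sorted(DRUG_FINGERPRINT_VIEWS):
        raise ValueError(
            f"expected the six fingerprint views {sorted(DRUG_FINGERPRINT_VIEWS)}, "
            f"got {names}"
        )
    return snf_fuse(views, k=k, t=t, mu=mu)


def fill_sparse_view(
    view: SimilarityView, fused_smiles: FusedSimilarity
) -> CompletedView:
    """Replace zero-source rows/columns of a sparse view with fused rows.

    For every entity flagged in the view's ``zero_row_mask`` (its source
    feature row was all-zero, i.e. the database had no record), row r and
    column r of S are overwritten with row r of the fused fingerprint
    network (rescaled into [0,1] if needed); every other entry is untouched
    and the diagonal is re-forced to 1.
    """
    if view.index.ids != fused_smiles.index.ids:
        raise ValueError("view and fused matrix must share one EntityIndex")
    S = view.S.copy()
    fill_rows = np.flatnonzero(view.zero_row_mask)
    F = fused_smiles.S
    fmax = F.max()
    if fmax > 1.0:
        F = F / fmax
    for r in fill_rows:
        S[r, :] = F[r, :]
        S[:, r] = F[r, :]
    # row r and column r receive the same symmetric fused row, so S stays
    # exactly symmetric; only the diagonal needs restoring
    np.fill_diagonal(S, 1.0)
    completed = SimilarityView(
        index=view.index,
        view_name=view.view_name,
        S=np.clip(S, 0.0, 1.0),
        zero_row_mask=np.zeros(len(view.index), dtype=bool),
        metric=view.metric,
    )
    return CompletedView(
        base=completed,
        filled_entities=frozenset(view.index.ids[r] for r in fill_rows),
    )


def fuse_all_drug_views(
    views: Sequence[SimilarityView],
    k: int | None = None,
    t: int = 20,
    mu: float = 0.5,
) -> FusedSimilarity:
    """Fuse the full set of 12 drug similarity views into SM_fusion."""
    if len(views) != 12:
        raise ValueError(f"expected 12 drug views, got {len(views)}")
    return snf_fuse(views, k=k, t=t, mu=mu)
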