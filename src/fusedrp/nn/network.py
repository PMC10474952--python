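"""The multi-view interaction network for IC50 regression.

Architecture, per drug-cell pair (d_i, c_j):

1. Per-view linear projections (no bias): each of the 12 drug similarity
   rows g_k is mapped to g'_k = g_k G_k in R^s, and each of the 4 cell
   feature rows h_l to h'_l = h_l H_l.
2. Interaction module: all K x L outer-product maps g'_k (x) h'_l (rank-1,
   s x s) are stacked as channels of a CNN (two residual blocks + one conv
   layer + global max pool); all K x L elementwise products g'_k (.) h'_l
   are concatenated and passed through a four-layer MLP.
3. Entity embeddings: an MLP over the drug's fused-similarity row, an MLP
   over the concatenated projected drug vectors (their concatenation is the
   drug embedding), and an MLP over the concatenated projected cell vectors.
4. Head: the four embeddings are concatenated and mapped to a scalar IC50
   by a four-layer fully connected head.

All passes are NumPy; backward is hand-written and verified against
numerical gradients in the test suite.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .layers import (
    Conv2d,
    Dense,
    GlobalMaxPool2d,
    Layer,
    MLP,
    ReLU,
    ResidualBlock2d,
)

__all__ = ["ModelSpec", "InteractionNetwork"]


@dataclass(frozen=True)
class ModelSpec:
    """Architecture constants; defaults follow the full-scale configuration."""

    s: int = 128
    n_drug_views: int = 12
    n_cell_views: int = 4
    cnn_channels: tuple[int, int, int] = (32, 32, 32)
    cnn_kernel: int = 3
    inner_mlp_sizes: tuple[int, ...] = (1024, 1024, 512, 128)
    head_sizes: tuple[int, ...] = (512, 256, 128, 1)
    #: start the drug projections G_k at zero.  Similarity rows of entities
    #: unseen in training hit projection rows that receive no data gradient;
    #: with random init those rows inject noise at test time (cold-start),
    #: with zero init they contribute nothing until trained.
    drug_proj_zero_init: bool = False

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError("projection dim s must be positive")
        if self.head_sizes[-1] != 1:
            raise ValueError("prediction head must end in one unit")
        if self.cnn_kernel > self.s:
            raise ValueError(
                f"kernel {self.cnn_kernel} larger than map size s={self.s}"
            )

    @property
    def n_maps(self) -> int:
        return self.n_drug_views * self.n_cell_views

    @classmethod
    def small(cls, n_drug_views: int = 12, n_cell_views: int = 4) -> "ModelSpec":
        """Desk-scale configuration for synthetic benchmarks and tests."""
        return cls(
            s=8,
            n_drug_views=n_drug_views,
            n_cell_views=n_cell_views,
            cnn_channels=(16, 16, 16),
            inner_mlp_sizes=(128, 128, 64, 32),
            head_sizes=(64, 32, 16, 1),
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        for key in ("cnn_channels", "inner_mlp_sizes", "head_sizes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


class InteractionNetwork(Layer):
    """Full forward/backward graph; inputs are per-view row batches."""

    def __init__(
        self,
        spec: ModelSpec,
        drug_widths: Sequence[int],
        fused_width: int,
        cell_widths: Sequence[int],
        rng: np.random.Generator,
        dtype=np.float64,
    ) -> None:
        super().__init__()
        if len(drug_widths) != spec.n_drug_views:
            raise ValueError(
                f"{len(drug_widths)} drug widths for {spec.n_drug_views} views"
            )
        if len(cell_widths) != spec.n_cell_views:
            raise ValueError(
                f"{len(cell_widths)} cell widths for {spec.n_cell_views} views"
            )
        self.spec = spec
        self.drug_widths = tuple(int(w) for w in drug_widths)
        self.fused_width = int(fused_width)
        self.cell_widths = tuple(int(w) for w in cell_widths)
        s = spec.s

        self.G = [Dense(w, s, rng, bias=False, dtype=dtype) for w in self.drug_widths]
        self.H = [Dense(w, s, rng, bias=False, dtype=dtype) for w in self.cell_widths]
        if spec.drug_proj_zero_init:
            for G in self.G:
                G.params["W"][...] = 0.0

        c1, c2, c3 = spec.cnn_channels
        self.res1 = ResidualBlock2d(spec.n_maps, c1, spec.cnn_kernel, rng, dtype)
        self.res2 = ResidualBlock2d(c1, c2, spec.cnn_kernel, rng, dtype)
        self.conv3 = Conv2d(c2, c3, spec.cnn_kernel, rng, dtype)
        self.cnn_relu = ReLU()
        self.gmp = GlobalMaxPool2d()

        self.mlp_inner = MLP(spec.n_maps * s, spec.inner_mlp_sizes, rng,
                             relu_last=False, dtype=dtype)
        self.mlp_fused = MLP(self.fused_width, (s, s), rng, relu_last=True,
                             dtype=dtype)
        self.mlp_drug = MLP(spec.n_drug_views * s, (s, s), rng, relu_last=True,
                            dtype=dtype)
        self.mlp_cell = MLP(spec.n_cell_views * s, (s, s), rng, relu_last=True,
                            dtype=dtype)

        self.z_dim = (c3 + spec.inner_mlp_sizes[-1] + 2 * s + s)
        self.head = MLP(self.z_dim, spec.head_sizes, rng, relu_last=False,
                        dtype=dtype)

    # -- composition ------------------------------------------------------

    def layers(self):
        for m in (*self.G, *self.H, self.res1, self.res2, self.conv3,
                  self.mlp_inner, self.mlp_fused, self.mlp_drug,
                  self.mlp_cell, self.head):
            yield from m.layers()

    # -- spec operations ---------------------------------------------------

    def project(
        self,
        drug_rows: Sequence[np.ndarray],
        cell_rows: Sequence[np.ndarray],
    ) -> tuple[np.ndarray, np.ndarray]:
        """Projected drug/cell vectors, shapes (B, K, s) and (B, L, s)."""
        self._check_widths(drug_rows, cell_rows)
        gs = np.stack([G.forward(x) for G, x in zip(self.G, drug_rows)], axis=1)
        hs = np.stack([H.forward(x) for H, x in zip(self.H, cell_rows)], axis=1)
        return gs, hs

    @staticmethod
    def interaction_maps(
        gs: np.ndarray, hs: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Outer maps (B, K*L, s, s) and inner vectors (B, K*L, s).

        outer[(k,l)][p,q] = g'_k[p] * h'_l[q]; inner[(k,l)] = g'_k . h'_l
        (elementwise), i.e. the diagonal of the outer map.
        """
        B, K, s = gs.shape
        L = hs.shape[1]
        outer = np.einsum("bkp,blq->bklpq", gs, hs, optimize=True)
        inner = np.einsum("bkp,blp->bklp", gs, hs, optimize=True)
        return outer.reshape(B, K * L, s, s), inner.reshape(B, K * L, s)

    # -- forward / backward -------------------------------------------------

    def forward_pair(
        self,
        drug_rows: Sequence[np.ndarray],
        fused_rows: np.ndarray,
        cell_rows: Sequence[np.ndarray],
    ) -> np.ndarray:
        """Predicted IC50 per pair, shape (B,)."""
        gs, hs = self.project(drug_rows, cell_rows)
        B, K, s = gs.shape
        L = hs.shape[1]
        self._gs, self._hs = gs, hs
        self._drug_rows = drug_rows

        outer, inner = self.interaction_maps(gs, hs)
        o = self.res1.forward(outer)
        o = self.res2.forward(o)
        o = self.conv3.forward(o)
        o = self.cnn_relu.forward(o)
        outer_emb = self.gmp.forward(o)

        inner_emb = self.mlp_inner.forward(inner.reshape(B, K * L * s))
        fused_emb = self.mlp_fused.forward(fused_rows)
        drug_emb = self.mlp_drug.forward(gs.reshape(B, K * s))
        cell_emb = self.mlp_cell.forward(hs.reshape(B, L * s))

        z = np.concatenate([outer_emb, inner_emb, fused_emb, drug_emb, cell_emb],
                           axis=1)
        self._split = np.cumsum([outer_emb.shape[1], inner_emb.shape[1],
                                 fused_emb.shape[1], drug_emb.shape[1]])
        return self.head.forward(z)[:, 0]

    def backward_pair(self, dpred: np.ndarray) -> None:
        """Backpropagate d(loss)/d(pred); parameter grads accumulate."""
        gs, hs = self._gs, self._hs
        B, K, s = gs.shape
        L = hs.shape[1]

        dz = self.head.backward(dpred[:, None])
        d_outer_emb, d_inner_emb, d_fused_emb, d_drug_emb, d_cell_emb = \
            np.split(dz, self._split, axis=1)

        do = self.gmp.backward(d_outer_emb)
        do = self.cnn_relu.backward(do)
        do = self.conv3.backward(do)
        do = self.res2.backward(do)
        d_outer = self.res1.backward(do).reshape(B, K, L, s, s)

        d_inner = self.mlp_inner.backward(d_inner_emb).reshape(B, K, L, s)

        dgs = np.einsum("bklpq,blq->bkp", d_outer, hs, optimize=True)
        dhs = np.einsum("bklpq,bkp->blq", d_outer, gs, optimize=True)
        dgs += np.einsum("bklp,blp->bkp", d_inner, hs, optimize=True)
        dhs += np.einsum("bklp,bkp->blp", d_inner, gs, optimize=True)

        self.mlp_fused.backward(d_fused_emb)
        dgs += self.mlp_drug.backward(d_drug_emb).reshape(B, K, s)
        dhs += self.mlp_cell.backward(d_cell_emb).reshape(B, L, s)

        for k, G in enumerate(self.G):
            G.backward(dgs[:, k, :])
        for l, H in enumerate(self.H):
            H.backward(dhs[:, l, :])

    def entity_embed(
        self,
        gs: np.ndarray,
        hs: np.ndarray,
        fused_rows: np.ndarray,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Drug embedding (fused-MLP output || drug-MLP output) and cell embedding."""
        B, K, s = gs.shape
        L = hs.shape[1]
        fused_emb = self.mlp_fused.forward(fused_rows)
        drug_part = self.mlp_drug.forward(gs.reshape(B, K * s))
        cell_emb = self.mlp_cell.forward(hs.reshape(B, L * s))
        return np.concatenate([fused_emb, drug_part], axis=1), cell_emb

    # -- helpers ------------------------------------------------------------

    def _check_widths(self, drug_rows, cell_rows) -> None:
        if len(drug_rows) != len(self.G) or len(cell_rows) != len(self.H):
            raise ValueError("view count mismatch with construction-time layout")
        for k, x in enumerate(drug_rows):
            if x.shape[1] != self.drug_widths[k]:
                raise ValueError(
                    f"drug view {k}: width {x.shape[1]} != {self.drug_widths[k]}"
                )
        for l, x in enumerate(cell_rows):
            if x.shape[1] != self.cell_widths[l]:
                raise ValueError(
                    f"cell view {l}: width {x.shape[1]} != {self.cell_widths[l]}"
                )
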