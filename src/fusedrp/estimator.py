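"""scikit-learn style estimators over the interaction network.

``PairFeatureBuilder`` turns (drug index, cell index) pairs into one wide
numeric row by concatenating, per pair, the drug's row of each similarity
view, its row of the fused network, and the cell's row of each cell view —
so the downstream regressor sees a plain 2-D array and composes with
sklearn pipelines and model selection.

``DrugResponseRegressor`` wraps the NumPy interaction network with
MSE loss, Adam (default lr 1e-4, weight decay 3e-4) and patience-based
early stopping on a validation split.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .nn.layers import Layer
from .nn.network import InteractionNetwork, ModelSpec
from .nn.optim import Adam

__all__ = ["PairFeatureBuilder", "DrugResponseRegressor", "ViewLayout"]


class ViewLayout:
    """Column layout of the wide pair-feature array.

    Ordered list of (kind, name, width) with kind in {"drug", "fused",
    "cell"}; drug views come first, then the fused row, then cell views.
    """

    def __init__(self, entries: Sequence[tuple[str, str, int]]) -> None:
        self.entries = [(str(k), str(n), int(w)) for k, n, w in entries]
        kinds = [k for k, _, _ in self.entries]
        if kinds.count("fused") != 1:
            raise ValueError("layout needs exactly one fused block")
        self.drug_widths = [w for k, _, w in self.entries if k == "drug"]
        self.fused_width = next(w for k, _, w in self.entries if k == "fused")
        self.cell_widths = [w for k, _, w in self.entries if k == "cell"]
        self.total_width = sum(w for _, _, w in self.entries)
        self._offsets = np.cumsum([0] + [w for _, _, w in self.entries])

    @property
    def n_drug_views(self) -> int:
        return len(self.drug_widths)

    @property
    def n_cell_views(self) -> int:
        return len(self.cell_widths)

    def split(self, X: np.ndarray):
        """Slice a wide array into (drug_rows list, fused, cell_rows list)."""
        if X.shape[1] != self.total_width:
            raise ValueError(
                f"X has width {X.shape[1]}, layout expects {self.total_width}"
            )
        blocks = [X[:, self._offsets[i]: self._offsets[i + 1]]
                  for i in range(len(self.entries))]
        drug, fused, cell = [], None, []
        for (kind, _, _), b in zip(self.entries, blocks):
            if kind == "drug":
                drug.append(b)
            elif kind == "fused":
                fused = b
            else:
                cell.append(b)
        return drug, fused, cell

    def __eq__(self, other) -> bool:
        return isinstance(other, ViewLayout) and self.entries == other.entries

    def __repr__(self) -> str:
        return f"ViewLayout({self.entries!r})"


class PairFeatureBuilder(TransformerMixin, BaseEstimator):
    """Map integer (drug, cell) pairs to wide per-pair feature rows.

    Parameters
    ----------
    drug_views : list of (name, (n, n) array) — the 12 drug similarity views.
    fused : (n, n) array — the fused drug network.
    cell_views : list of (name, (m, w) array) — the 4 cell views.
    standardize : list of bool per cell view; True z-scores that view's
        columns using statistics from the cell lines seen in ``fit`` (the
        training pairs), so test-only cell lines reuse train statistics.
    """

    def __init__(self, drug_views, fused, cell_views,
                 standardize: Sequence[bool] | None = None) -> None:
        self.drug_views = drug_views
        self.fused = fused
        self.cell_views = cell_views
        self.standardize = standardize

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=int)
        std = self.standardize
        if std is None:
            std = [name in ("exp", "mu", "cnv") for name, _ in self.cell_views]
        if len(std) != len(self.cell_views):
            raise ValueError("standardize must have one flag per cell view")
        self._std_flags = list(std)
        train_cells = np.unique(X[:, 1])
        self.cell_stats_ = []
        for flag, (_, M) in zip(self._std_flags, self.cell_views):
            if flag:
                sub = np.asarray(M, dtype=float)[train_cells]
                mu = sub.mean(axis=0)
                sd = sub.std(axis=0)
                sd = np.where(sd > 0, sd, 1.0)
                self.cell_stats_.append((mu, sd))
            else:
                self.cell_stats_.append(None)
        entries = [("drug", name, np.asarray(M).shape[1])
                   for name, M in self.drug_views]
        entries.append(("fused", "fused", np.asarray(self.fused).shape[1]))
        entries += [("cell", name, np.asarray(M).shape[1])
                    for name, M in self.cell_views]
        self.layout_ = ViewLayout(entries)
        self.n_features_in_ = 2
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "layout_")
        X = np.asarray(X, dtype=int)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_pairs, 2) of [drug_idx, cell_idx]")
        d_idx, c_idx = X[:, 0], X[:, 1]
        blocks = [np.asarray(M, dtype=float)[d_idx] for _, M in self.drug_views]
        blocks.append(np.asarray(self.fused, dtype=float)[d_idx])
        for (name, M), stats in zip(self.cell_views, self.cell_stats_):
            rows = np.asarray(M, dtype=float)[c_idx]
            if stats is not None:
                mu, sd = stats
                rows = (rows - mu) / sd
            blocks.append(rows)
        return np.concatenate(blocks, axis=1)


class DrugResponseRegressor(RegressorMixin, BaseEstimator):
    """IC50 regressor: projections + interaction module + MLP head.

    Parameters
    ----------
    layout : ViewLayout describing how columns of X split into views.
    spec : ModelSpec or None; None builds the default spec adapted to the
        layout's view counts.
    lr, weight_decay : Adam settings (defaults 1e-4 and 3e-4).
    batch_size, max_epochs, patience : training loop controls; training
        stops when validation loss has not improved for ``patience`` epochs.
    n_ensemble : number of independently initialized networks trained;
        predictions are their average (variance reduction on small data).
    validation_fraction : used when ``fit`` receives no explicit
        validation set.
    random_state : seeds parameter init and batch shuffling.
    dtype : np.float32 (fast) or np.float64.
    """

    def __init__(self, layout=None, spec=None, lr=1e-4, weight_decay=3e-4,
                 decoupled_weight_decay=False, batch_size=128, max_epochs=300,
                 patience=10, n_ensemble=1, validation_fraction=0.1,
                 shuffle=True, random_state=None, dtype=np.float32, verbose=0):
        self.layout = layout
        self.spec = spec
        self.lr = lr
        self.weight_decay = weight_decay
        self.decoupled_weight_decay = decoupled_weight_decay
        self.n_ensemble = n_ensemble
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.shuffle = shuffle
        self.random_state = random_state
        self.dtype = dtype
        self.verbose = verbose

    # -- sklearn plumbing ----------------------------------------------------

    def _resolved_spec(self) -> ModelSpec:
        if self.spec is not None:
            spec = self.spec
            if spec.n_drug_views != self.layout.n_drug_views or \
               spec.n_cell_views != self.layout.n_cell_views:
                raise ValueError(
                    "spec view counts do not match layout: "
                    f"spec ({spec.n_drug_views}x{spec.n_cell_views}) vs layout "
                    f"({self.layout.n_drug_views}x{self.layout.n_cell_views})"
                )
            return spec
        return ModelSpec(n_drug_views=self.layout.n_drug_views,
                         n_cell_views=self.layout.n_cell_views)

    def fit(self, X, y, validation_data=None):
        if self.layout is None:
            raise ValueError("layout is required (see PairFeatureBuilder.layout_)")
        X = np.asarray(X, dtype=self.dtype)
        y = np.asarray(y, dtype=self.dtype).ravel()
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        if X.shape[0] == 0:
            raise ValueError("empty training set")
        rng = np.random.default_rng(self.random_state)
        spec = self._resolved_spec()

        if validation_data is not None:
            Xv, yv = validation_data
            Xv = np.asarray(Xv, dtype=self.dtype)
            yv = np.asarray(yv, dtype=self.dtype).ravel()
            Xt, yt = X, y
        else:
            n_val = max(1, int(round(self.validation_fraction * X.shape[0])))
            if n_val >= X.shape[0]:
                raise ValueError("validation split leaves no training data")
            perm = rng.permutation(X.shape[0])
            Xv, yv = X[perm[:n_val]], y[perm[:n_val]]
            Xt, yt = X[perm[n_val:]], y[perm[n_val:]]
        if Xv.shape[0] == 0:
            raise ValueError("empty validation set")

        self.networks_ = []
        self.histories_ = []
        self.best_epochs_ = []
        best_vals = []
        for _ in range(int(self.n_ensemble)):
            member_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
            net, history, best_epoch, best_val = self._fit_single(
                spec, Xt, yt, Xv, yv, member_rng)
            self.networks_.append(net)
            self.histories_.append(history)
            self.best_epochs_.append(best_epoch)
            best_vals.append(best_val)

        self.network_ = self.networks_[0]
        self.spec_ = spec
        self.history_ = self.histories_[0]
        self.best_epoch_ = self.best_epochs_[0]
        self.best_val_loss_ = best_vals[0]
        self.n_features_in_ = X.shape[1]
        return self

    def _fit_single(self, spec, Xt, yt, Xv, yv, rng):
        net = InteractionNetwork(
            spec,
            drug_widths=self.layout.drug_widths,
            fused_width=self.layout.fused_width,
            cell_widths=self.layout.cell_widths,
            rng=rng,
            dtype=self.dtype,
        )
        opt = Adam(net, lr=self.lr, weight_decay=self.weight_decay,
                   decoupled=self.decoupled_weight_decay)

        best_val = np.inf
        best_state = net.state()
        best_epoch = 0
        epochs_since_best = 0
        history: list[dict] = []
        n = Xt.shape[0]
        for epoch in range(1, self.max_epochs + 1):
            order = rng.permutation(n) if self.shuffle else np.arange(n)
            train_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start: start + self.batch_size]
                preds = self._forward(net, Xt[idx])
                err = preds - yt[idx]
                train_loss += float(np.sum(err**2))
                net.zero_grad()
                net.backward_pair((2.0 / len(idx)) * err)
                opt.step()
            train_loss /= n
            val_loss = float(np.mean(
                (self._predict_batches(net, Xv) - yv) ** 2))
            history.append({"epoch": epoch, "train_loss": train_loss,
                            "val_loss": val_loss})
            if self.verbose:
                print(f"epoch {epoch:4d}  train {train_loss:.4f}  "
                      f"val {val_loss:.4f}")
            if val_loss < best_val:
                best_val = val_loss
                best_state = net.state()
                best_epoch = epoch
                epochs_since_best = 0
            else:
                epochs_since_best += 1
                if self.patience is not None and \
                        epochs_since_best >= self.patience:
                    break

        net.load_state(best_state)
        return net, pd.DataFrame(history), best_epoch, best_val

    def _forward(self, net: InteractionNetwork, X: np.ndarray) -> np.ndarray:
        drug, fused, cell = self.layout.split(X)
        return net.forward_pair(drug, fused, cell)

    def _predict_batches(self, net, X, batch: int = 512) -> np.ndarray:
        out = [self._forward(net, X[i: i + batch])
               for i in range(0, X.shape[0], batch)]
        return np.concatenate(out) if out else np.empty(0)

    def predict(self, X) -> np.ndarray:
        """Predicted IC50 per pair; ensemble members' predictions averaged."""
        check_is_fitted(self, "networks_")
        X = np.asarray(X, dtype=self.dtype)
        preds = [np.asarray(self._predict_batches(net, X), dtype=np.float64)
                 for net in self.networks_]
        return np.mean(preds, axis=0)
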