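"""Behavioural tests of the interaction model and its training loop."""

import numpy as np
import pandas as pd
import pytest

from fusedrp.estimator import DrugResponseRegressor, PairFeatureBuilder, ViewLayout
from fusedrp.nn.network import InteractionNetwork, ModelSpec


def tiny_net(seed=0, s=4, n_drug=3, n_cell=2, widths=(5, 5, 5), fused=5,
             cell_widths=(6, 4)):
    rng = np.random.default_rng(seed)
    spec = ModelSpec(s=s, n_drug_views=n_drug, n_cell_views=n_cell,
                     cnn_channels=(3, 3, 2), inner_mlp_sizes=(7, 5),
                     head_sizes=(6, 1))
    return spec, InteractionNetwork(spec, drug_widths=list(widths),
                                    fused_width=fused,
                                    cell_widths=list(cell_widths), rng=rng)


def tiny_inputs(rng, B=4, widths=(5, 5, 5), fused=5, cell_widths=(6, 4)):
    return ([rng.normal(size=(B, w)) for w in widths],
            rng.normal(size=(B, fused)),
            [rng.normal(size=(B, w)) for w in cell_widths])


class TestProjection:
    def test_identity_projection_preserves_input(self):
        spec, net = tiny_net(s=5, widths=(5, 5, 5), cell_widths=(5, 5))
        for G in net.G:
            G.params["W"] = np.eye(5)
        x = np.arange(10, dtype=float).reshape(2, 5)
        gs, _ = net.project([x, x, x], [x, x])
        for k in range(3):
            np.testing.assert_array_equal(gs[:, k, :], x)

    def test_zero_row_projects_to_zero(self):
        _, net = tiny_net()
        rng = np.random.default_rng(3)
        drug, fused, cell = tiny_inputs(rng)
        drug[0][:] = 0.0
        gs, _ = net.project(drug, cell)
        np.testing.assert_array_equal(gs[:, 0, :], 0.0)

    def test_shape_contract(self):
        rng = np.random.default_rng(0)
        spec = ModelSpec(s=8, n_drug_views=12, n_cell_views=4,
                         cnn_channels=(4, 4, 4), inner_mlp_sizes=(8, 8),
                         head_sizes=(8, 1))
        net = InteractionNetwork(spec, drug_widths=[20] * 12, fused_width=20,
                                 cell_widths=[15, 15, 15, 20], rng=rng)
        drug = [rng.normal(size=(3, 20)) for _ in range(12)]
        cell = [rng.normal(size=(3, w)) for w in (15, 15, 15, 20)]
        gs, hs = net.project(drug, cell)
        assert gs.shape == (3, 12, 8)
        assert hs.shape == (3, 4, 8)

    def test_width_mismatch_raises(self):
        _, net = tiny_net()
        rng = np.random.default_rng(0)
        drug, fused, cell = tiny_inputs(rng)
        drug[1] = rng.normal(size=(4, 7))
        with pytest.raises(ValueError, match="drug view 1"):
            net.project(drug, cell)


class TestInteractionMaps:
    def test_hand_arithmetic(self):
        gs = np.array([[[1.0, 2.0]]])
        hs = np.array([[[3.0, 4.0]]])
        outer, inner = InteractionNetwork.interaction_maps(gs, hs)
        np.testing.assert_array_equal(outer[0, 0], [[3, 4], [6, 8]])
        np.testing.assert_array_equal(inner[0, 0], [3, 8])

    def test_counts_are_view_products(self):
        rng = np.random.default_rng(0)
        gs = rng.normal(size=(2, 12, 8))
        hs = rng.normal(size=(2, 4, 8))
        outer, inner = InteractionNetwork.interaction_maps(gs, hs)
        assert outer.shape == (2, 48, 8, 8)
        assert inner.shape == (2, 48, 8)

    def test_outer_maps_are_rank_one(self):
        rng = np.random.default_rng(1)
        gs = rng.normal(size=(1, 3, 6))
        hs = rng.normal(size=(1, 2, 6))
        outer, _ = InteractionNetwork.interaction_maps(gs, hs)
        for m in range(6):
            assert np.linalg.matrix_rank(outer[0, m]) <= 1

    def test_inner_equals_outer_diagonal(self):
        rng = np.random.default_rng(2)
        gs = rng.normal(size=(3, 4, 5))
        hs = rng.normal(size=(3, 2, 5))
        outer, inner = InteractionNetwork.interaction_maps(gs, hs)
        np.testing.assert_allclose(
            inner, np.diagonal(outer, axis1=2, axis2=3), atol=1e-15)


class TestResidualContract:
    def test_zero_residual_branch_is_identity(self):
        from fusedrp.nn.layers import ResidualBlock2d
        rng = np.random.default_rng(0)
        block = ResidualBlock2d(3, 3, 3, rng)
        block.zero_residual_()
        x = rng.normal(size=(2, 3, 5, 5))
        np.testing.assert_array_equal(block.forward(x), x)

    def test_zero_residual_with_projection_shortcut(self):
        from fusedrp.nn.layers import ResidualBlock2d
        rng = np.random.default_rng(0)
        block = ResidualBlock2d(3, 5, 3, rng)
        block.zero_residual_()
        x = rng.normal(size=(2, 3, 4, 4))
        np.testing.assert_allclose(block.forward(x),
                                   block.shortcut.forward(x), atol=1e-15)

    def test_channel_permutation_changes_output(self):
        """The CNN is not channel-permutation invariant (documented)."""
        _, net = tiny_net(seed=4)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(1, 6, 4, 4))
        y1 = net.res1.forward(x)
        y2 = net.res1.forward(x[:, ::-1].copy())
        assert not np.allclose(y1, y2)


class TestForward:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        drug, fused, cell = tiny_inputs(rng)
        _, net1 = tiny_net(seed=11)
        _, net2 = tiny_net(seed=11)
        np.testing.assert_array_equal(net1.forward_pair(drug, fused, cell),
                                      net2.forward_pair(drug, fused, cell))

    def test_batch_equals_single(self):
        rng = np.random.default_rng(9)
        drug, fused, cell = tiny_inputs(rng, B=5)
        _, net = tiny_net(seed=2)
        batch = net.forward_pair(drug, fused, cell)
        singles = [net.forward_pair([d[i:i+1] for d in drug],
                                    fused[i:i+1],
                                    [c[i:i+1] for c in cell])[0]
                   for i in range(5)]
        np.testing.assert_allclose(batch, singles, atol=1e-6)

    def test_entity_embed_widths(self):
        spec, net = tiny_net()
        rng = np.random.default_rng(0)
        drug, fused, cell = tiny_inputs(rng)
        gs, hs = net.project(drug, cell)
        d_emb, c_emb = net.entity_embed(gs, hs, fused)
        assert d_emb.shape == (4, 2 * spec.s)
        assert c_emb.shape == (4, spec.s)
        assert (d_emb >= 0).all() and (c_emb >= 0).all()  # ReLU outputs


def _toy_layout(n=6, m=5, g=4):
    entries = [("drug", f"v{k}", n) for k in range(3)]
    entries.append(("fused", "fused", n))
    entries += [("cell", "exp", g), ("cell", "cd", m)]
    return ViewLayout(entries)


def _toy_data(seed=0, n_pairs=50):
    rng = np.random.default_rng(seed)
    layout = _toy_layout()
    X = rng.normal(size=(n_pairs, layout.total_width))
    w = rng.normal(size=layout.total_width)
    y = np.tanh(X @ w / 4.0)
    return layout, X, y


def _toy_spec():
    return ModelSpec(s=4, n_drug_views=3, n_cell_views=2,
                     cnn_channels=(3, 3, 2), inner_mlp_sizes=(16, 8),
                     head_sizes=(16, 1))


class TestTraining:
    def test_overfits_small_dataset(self):
        layout, X, y = _toy_data()
        model = DrugResponseRegressor(
            layout=layout, spec=_toy_spec(), lr=3e-3, weight_decay=0.0,
            batch_size=16, max_epochs=500, patience=None,
            random_state=0, dtype=np.float64)
        # explicit validation set so every pair is trained on (capacity check)
        model.fit(X, y, validation_data=(X[:5], y[:5]))
        train_mse = float(np.mean((model.predict(X) - y) ** 2))
        assert train_mse < 0.01

    def test_patience_arithmetic(self, monkeypatch):
        """Monotonically worsening validation loss stops training at epoch 11."""
        layout, X, y = _toy_data()
        model = DrugResponseRegressor(
            layout=layout, spec=_toy_spec(), patience=10, max_epochs=100,
            random_state=0)
        # force a strictly increasing validation-loss sequence
        counter = {"n": 0}

        def fake_eval(net, Xv, batch=512):
            counter["n"] += 1
            return np.full(5, counter["n"], dtype=float)

        monkeypatch.setattr(model, "_predict_batches", fake_eval)
        model.fit(X, y, validation_data=(X[:5], np.zeros(5)))
        assert len(model.history_) == 11
        assert model.best_epoch_ == 1

    def test_fixed_seed_reproducible_history(self):
        layout, X, y = _toy_data()
        kwargs = dict(layout=layout, spec=_toy_spec(), max_epochs=5,
                      patience=None, random_state=42)
        h1 = DrugResponseRegressor(**kwargs).fit(X, y).history_
        h2 = DrugResponseRegressor(**kwargs).fit(X, y).history_
        pd.testing.assert_frame_equal(h1, h2)

    def test_empty_split_rejected(self):
        layout, X, y = _toy_data()
        model = DrugResponseRegressor(layout=layout, spec=_toy_spec())
        with pytest.raises(ValueError, match="empty"):
            model.fit(X[:0], y[:0])

    def test_best_checkpoint_restored(self):
        layout, X, y = _toy_data()
        model = DrugResponseRegressor(
            layout=layout, spec=_toy_spec(), lr=3e-3, max_epochs=40,
            patience=None, random_state=1)
        model.fit(X, y, validation_data=(X[:10], y[:10]))
        val_mse = float(np.mean((model.predict(X[:10]) - y[:10]) ** 2))
        assert val_mse == pytest.approx(model.best_val_loss_, rel=1e-4)

    def test_sklearn_clone_and_params_roundtrip(self):
        from sklearn.base import clone
        layout = _toy_layout()
        model = DrugResponseRegressor(layout=layout, lr=5e-4)
        cloned = clone(model)
        assert cloned.get_params()["lr"] == 5e-4
        assert cloned.get_params()["layout"] == layout


class TestPairFeatureBuilder:
    def test_transform_concatenates_rows(self):
        rng = np.random.default_rng(0)
        n, m = 4, 3
        drug_views = [(f"v{k}", rng.random((n, n))) for k in range(2)]
        fused = rng.random((n, n))
        cell_views = [("exp", rng.random((m, 5))), ("cd", rng.random((m, m)))]
        fb = PairFeatureBuilder(drug_views, fused, cell_views,
                                standardize=[False, False])
        pairs = np.array([[0, 1], [2, 2]])
        X = fb.fit_transform(pairs)
        row0 = np.concatenate([drug_views[0][1][0], drug_views[1][1][0],
                               fused[0], cell_views[0][1][1],
                               cell_views[1][1][1]])
        np.testing.assert_array_equal(X[0], row0)

    def test_standardization_uses_train_cells_only(self):
        rng = np.random.default_rng(1)
        n, m = 3, 6
        drug_views = [("v", np.eye(n))]
        fused = np.eye(n)
        M = rng.normal(loc=5.0, size=(m, 4))
        fb = PairFeatureBuilder(drug_views, fused, [("exp", M)],
                                standardize=[True])
        train_pairs = np.array([[0, 0], [1, 1], [2, 2]])
        fb.fit(train_pairs)
        mu = M[:3].mean(axis=0)
        sd = M[:3].std(axis=0)
        X = fb.transform(np.array([[0, 4]]))
        np.testing.assert_allclose(X[0, -4:], (M[4] - mu) / sd, atol=1e-12)

    def test_model_spec_config_roundtrip(self):
        spec = ModelSpec.small()
        again = ModelSpec.from_dict(spec.to_dict())
        assert spec == again
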