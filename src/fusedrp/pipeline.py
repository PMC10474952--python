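"""Dataset splitting, metrics, feature-bank assembly and the full pipeline.

Split schemes
-------------
``random_811``  pairs split 8:1:1 into train/val/test.
``es1_drug_blind``  20% of drugs become blinded test drugs: every pair of a
    test drug goes to the test set and no test drug appears in any train or
    validation pair (the cold-start guarantee).  Of the remaining pairs,
    ~1/6 are validation.  ``es_mode="entities"`` instead partitions the
    selected entities 4:1:1 into test/val/train-visible buckets.
``es2_cell_blind``  the same, blinding cell lines.
``independent``  an externally supplied pair table is the test set verbatim.

Leakage guard: the IC50-profile features (M_CD / M_DC and the similarity
views derived from them) are always built from training-split triples only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .entities import (
    CELL_VIEW_ORDER,
    DRUG_FINGERPRINT_VIEWS,
    DRUG_VIEW_ORDER,
    EntityIndex,
    FusedSimilarity,
    SimilarityView,
)
from .estimator import DrugResponseRegressor, PairFeatureBuilder
from .featurize import (
    build_association_matrix,
    build_combined_score_matrix,
    build_fingerprint_matrices,
    build_ic50_profile_matrices,
)
from .fusion import COMPLETABLE_VIEWS, fill_sparse_view, fuse_all_drug_views, \
    fuse_smiles_views
from .nn.network import ModelSpec
from .similarity import build_all_views
from .synthetic import SyntheticBundle

__all__ = [
    "SplitScheme",
    "MetricsReport",
    "split_pairs",
    "evaluate",
    "build_feature_bank",
    "train_and_evaluate",
    "ablate_views",
    "run_pipeline",
]

SPLIT_KINDS = ("random_811", "es1_drug_blind", "es2_cell_blind", "independent")


@dataclass(frozen=True)
class SplitScheme:
    kind: str = "random_811"
    seed: int = 0
    blind_fraction: float = 0.2   # entity fraction blinded under ES1/ES2
    val_fraction: float = 1 / 6   # of remaining pairs under ES1/ES2
    es_mode: str = "pairs"        # "pairs" | "entities"

    def __post_init__(self) -> None:
        if self.kind not in SPLIT_KINDS:
            raise ValueError(f"kind must be one of {SPLIT_KINDS}")
        if self.es_mode not in ("pairs", "entities"):
            raise ValueError("es_mode must be 'pairs' or 'entities'")


@dataclass(frozen=True)
class MetricsReport:
    rmse: float
    mae: float
    pearson_r: float
    n_pairs: int
    scheme: SplitScheme | None = None

    def as_dict(self) -> dict:
        return {"rmse": self.rmse, "mae": self.mae,
                "pearson_r": self.pearson_r, "n_pairs": self.n_pairs}


def split_pairs(
    pairs: pd.DataFrame,
    scheme: SplitScheme,
    independent_pairs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Return a copy of ``pairs`` with a ``split`` column.

    ES1/ES2 guarantee that a blinded test entity has no train or validation
    pair.  ``independent`` keeps all of ``pairs`` for train/val (9:1) and
    appends the external table as the test set.
    """
    if len(pairs) < 10:
        raise ValueError("need at least 10 pairs to split")
    rng = np.random.default_rng(scheme.seed)
    out = pairs.copy().reset_index(drop=True)
    out["split"] = "train"

    if scheme.kind == "random_811":
        perm = rng.permutation(len(out))
        n_test = int(round(0.1 * len(out)))
        n_val = int(round(0.1 * len(out)))
        out.loc[perm[:n_test], "split"] = "test"
        out.loc[perm[n_test: n_test + n_val], "split"] = "val"
        return out

    if scheme.kind == "independent":
        if independent_pairs is None:
            raise ValueError("independent scheme needs an external pair table")
        perm = rng.permutation(len(out))
        n_val = int(round(0.1 * len(out)))
        out.loc[perm[:n_val], "split"] = "val"
        ext = independent_pairs.copy()
        ext["split"] = "test"
        return pd.concat([out, ext], ignore_index=True)

    col = "drug_id" if scheme.kind == "es1_drug_blind" else "cell_id"
    entities = np.array(sorted(out[col].unique()))
    if len(entities) < 6:
        raise ValueError(
            f"need >= 6 distinct {col} values for {scheme.kind}, "
            f"got {len(entities)}"
        )
    n_blind = max(1, int(round(scheme.blind_fraction * len(entities))))
    selected = rng.choice(entities, size=n_blind, replace=False)

    if scheme.es_mode == "entities":
        # split the selected entities 4:1:1 (test : val-only : train-visible)
        perm = rng.permutation(n_blind)
        n_test_e = max(1, int(round(n_blind * 4 / 6)))
        n_val_e = max(0, int(round(n_blind / 6)))
        test_e = set(selected[perm[:n_test_e]])
        val_e = set(selected[perm[n_test_e: n_test_e + n_val_e]])
        out.loc[out[col].isin(test_e), "split"] = "test"
        out.loc[out[col].isin(val_e), "split"] = "val"
        return out

    test_e = set(selected)
    is_test = out[col].isin(test_e)
    out.loc[is_test, "split"] = "test"
    # validation is entity-blind as well: early stopping must measure
    # cold-start generalization, so validation entities are disjoint from
    # training entities (their pairs amount to ~val_fraction of the rest)
    rest_entities = rng.permutation(
        np.array(sorted(set(out[col]) - test_e)))
    rest_pair_count = int((~is_test).sum())
    target_val = scheme.val_fraction * rest_pair_count
    val_e: set = set()
    acquired = 0
    for e in rest_entities:
        if acquired >= target_val:
            break
        val_e.add(e)
        acquired += int(((out[col] == e) & ~is_test).sum())
    out.loc[out[col].isin(val_e) & ~is_test, "split"] = "val"
    return out


def evaluate(predictions: np.ndarray, truths: np.ndarray,
             scheme: SplitScheme | None = None) -> MetricsReport:
    """RMSE, MAE and Pearson r between predictions and ground truth."""
    p = np.asarray(predictions, dtype=float).ravel()
    t = np.asarray(truths, dtype=float).ravel()
    if p.shape != t.shape:
        raise ValueError("predictions and truths must have equal length")
    if p.size < 2:
        raise ValueError("need at least 2 pairs to evaluate")
    if np.std(t) == 0:
        raise ValueError("constant ground truth: Pearson r undefined")
    rmse = float(np.sqrt(np.mean((p - t) ** 2)))
    mae = float(np.mean(np.abs(p - t)))
    # constant predictions (e.g. an untrained smoke run) leave r undefined
    r = float(stats.pearsonr(p, t)[0]) if np.std(p) > 0 else float("nan")
    return MetricsReport(rmse=rmse, mae=mae, pearson_r=r, n_pairs=p.size,
                         scheme=scheme)


# ---------------------------------------------------------------------------
# feature bank: everything the estimator needs, leakage-guarded
# ---------------------------------------------------------------------------

@dataclass
class FeatureBank:
    drug_views: list[tuple[str, np.ndarray]]   # 12 (name, n x n)
    fused: np.ndarray                          # n x n
    cell_views: list[tuple[str, np.ndarray]]   # 4 (name, m x w)
    drug_index: EntityIndex
    cell_index: EntityIndex
    fused_smiles: FusedSimilarity
    filled: dict[str, frozenset[str]]


def build_feature_bank(
    bundle: SyntheticBundle,
    train_pairs: pd.DataFrame,
    metric: str = "chebyshev",
    snf_k: int | None = None,
    snf_t: int = 20,
    snf_mu: float = 0.5,
    exclude_view: str | None = None,
) -> FeatureBank:
    """Assemble the drug/cell views and fused matrix from a raw bundle.

    ``train_pairs`` must be the training split only: the IC50-profile
    matrices (and their similarity views) are derived from it.
    ``exclude_view`` drops one drug or cell view (ablation runs).
    """
    drug_features = dict(build_fingerprint_matrices(
        bundle.drug_index, precomputed=bundle.fingerprints))
    for view, table in bundle.association_tables.items():
        fm = build_association_matrix(table, bundle.drug_index)
        fm.view_name = view
        drug_features[view] = fm
    drug_features["combined"] = build_combined_score_matrix(
        bundle.combined_table, bundle.drug_index)
    cd, dc = build_ic50_profile_matrices(
        train_pairs, bundle.drug_index, bundle.cell_index)
    drug_features["dc_profile"] = dc
    cell_features = dict(bundle.omics)
    cell_features["cd_profile"] = cd

    drug_views, cell_views = build_all_views(drug_features, cell_features,
                                             metric=metric)

    fused_smiles = fuse_smiles_views(
        [drug_views[v] for v in DRUG_FINGERPRINT_VIEWS],
        k=snf_k, t=snf_t, mu=snf_mu)

    completed: dict[str, np.ndarray] = {}
    filled: dict[str, frozenset[str]] = {}
    for name in DRUG_VIEW_ORDER:
        view = drug_views[name]
        if name in COMPLETABLE_VIEWS:
            cv = fill_sparse_view(view, fused_smiles)
            completed[name] = cv.S
            filled[name] = cv.filled_entities
            drug_views[name] = cv.base
        else:
            completed[name] = view.S

    fused_all = fuse_all_drug_views(
        [drug_views[v] for v in DRUG_VIEW_ORDER], k=snf_k, t=snf_t, mu=snf_mu)

    drug_list = [(name, completed[name]) for name in DRUG_VIEW_ORDER
                 if name != exclude_view]
    cell_list = []
    for name in CELL_VIEW_ORDER:
        if name == exclude_view:
            continue
        cv = cell_views[name]
        cell_list.append((name, cv.S if isinstance(cv, SimilarityView)
                          else cv.values))
    if exclude_view is not None and \
            len(drug_list) + len(cell_list) == len(DRUG_VIEW_ORDER) + len(CELL_VIEW_ORDER):
        raise ValueError(f"exclude_view {exclude_view!r} is not a known view")

    return FeatureBank(
        drug_views=drug_list,
        fused=fused_all.S,
        cell_views=cell_list,
        drug_index=bundle.drug_index,
        cell_index=bundle.cell_index,
        fused_smiles=fused_smiles,
        filled=filled,
    )


def _pairs_to_xy(pairs: pd.DataFrame, drug_index: EntityIndex,
                 cell_index: EntityIndex) -> tuple[np.ndarray, np.ndarray]:
    dpos, cpos = drug_index.positions, cell_index.positions
    P = np.column_stack([
        pairs["drug_id"].map(dpos).to_numpy(),
        pairs["cell_id"].map(cpos).to_numpy(),
    ]).astype(int)
    return P, pairs["ic50"].to_numpy(dtype=float)


def train_and_evaluate(
    bundle: SyntheticBundle,
    scheme: SplitScheme,
    spec: ModelSpec | None = None,
    exclude_view: str | None = None,
    metric: str = "chebyshev",
    train_kwargs: Mapping | None = None,
    random_state: int | None = None,
    independent_pairs: pd.DataFrame | None = None,
) -> tuple[MetricsReport, DrugResponseRegressor, pd.DataFrame]:
    """Split, build the leakage-guarded feature bank, train, evaluate.

    ``independent_pairs`` supplies the external test table for the
    ``independent`` scheme; its drugs/cells must resolve in the bundle's
    entity indices.
    """
    labeled = split_pairs(bundle.pairs, scheme,
                          independent_pairs=independent_pairs)
    train = labeled[labeled["split"] == "train"]
    val = labeled[labeled["split"] == "val"]
    test = labeled[labeled["split"] == "test"]
    if min(len(train), len(val), len(test)) == 0:
        raise ValueError("split produced an empty train/val/test set")

    bank = build_feature_bank(bundle, train, metric=metric,
                              exclude_view=exclude_view)
    Ptr, ytr = _pairs_to_xy(train, bank.drug_index, bank.cell_index)
    Pva, yva = _pairs_to_xy(val, bank.drug_index, bank.cell_index)
    Pte, yte = _pairs_to_xy(test, bank.drug_index, bank.cell_index)

    builder = PairFeatureBuilder(bank.drug_views, bank.fused,
                                 bank.cell_views).fit(Ptr)
    if spec is None:
        spec = ModelSpec.small(n_drug_views=builder.layout_.n_drug_views,
                               n_cell_views=builder.layout_.n_cell_views)
    kwargs = dict(lr=1e-3, weight_decay=3e-4, batch_size=128,
                  max_epochs=150, patience=10)
    if train_kwargs:
        kwargs.update(train_kwargs)
    model = DrugResponseRegressor(
        layout=builder.layout_, spec=spec,
        random_state=scheme.seed if random_state is None else random_state,
        **kwargs)
    model.fit(builder.transform(Ptr), ytr,
              validation_data=(builder.transform(Pva), yva))
    preds = model.predict(builder.transform(Pte))
    report = evaluate(preds, yte, scheme=scheme)
    return report, model, labeled


def ablate_views(
    bundle: SyntheticBundle,
    scheme: SplitScheme,
    spec: ModelSpec | None = None,
    train_kwargs: Mapping | None = None,
) -> pd.DataFrame:
    """Leave-one-view-out: 12 drug-view + 4 cell-view exclusion runs.

    Each run retrains from scratch with the model shapes adapted to the
    reduced view count (11x4 or 12x3 interaction pairs).
    """
    rows = []
    for name in (*DRUG_VIEW_ORDER, *CELL_VIEW_ORDER):
        report, model, _ = train_and_evaluate(
            bundle, scheme, spec=None if spec is None else spec,
            exclude_view=name, train_kwargs=train_kwargs)
        rows.append({"excluded_view": name, "n_maps": model.spec_.n_maps,
                     **report.as_dict()})
    return pd.DataFrame(rows)


def run_pipeline(
    bundle: SyntheticBundle,
    scheme: SplitScheme,
    out_dir: str | Path | None = None,
    spec: ModelSpec | None = None,
    train_kwargs: Mapping | None = None,
) -> MetricsReport:
    """End-to-end run; optionally serialize intermediates and the report."""
    report, model, labeled = train_and_evaluate(
        bundle, scheme, spec=spec, train_kwargs=train_kwargs)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        labeled.to_csv(out / "pairs_with_split.csv", index=False)
        model.history_.to_csv(out / "training_log.tsv", sep="\t", index=False)
        pd.DataFrame([report.as_dict()]).to_csv(out / "metrics.csv", index=False)
    return report
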