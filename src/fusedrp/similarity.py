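"""Row-wise similarity views from feature matrices.

The default metric is the Chebyshev (L-infinity) distance between feature
rows, D(a,b) = max_c |v_ac - v_bc|, mapped to a similarity.  The distance
to similarity transform is S = 1 - D when all pairwise distances already
lie in [0,1] (true for binary and unit-range views), otherwise distances
are first divided by the matrix maximum so S stays in [0,1].

Note that on binary feature rows the Chebyshev distance is 0/1-valued: two
drugs are maximally similar only when their rows coincide, so binary views
produce near-diagonal similarity matrices.  This is a property of the
metric, not a bug; the metric is pluggable.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
from scipy.spatial.distance import cdist

from .entities import (
    CELL_VIEW_ORDER,
    DRUG_ASSOCIATION_VIEWS,
    DRUG_FINGERPRINT_VIEWS,
    DRUG_VIEW_ORDER,
    EntityIndex,
    FeatureMatrix,
    SimilarityView,
)

__all__ = [
    "chebyshev_distance",
    "similarity_from_features",
    "build_all_views",
    "SUPPORTED_METRICS",
]

SUPPORTED_METRICS = ("chebyshev", "euclidean", "cosine", "cityblock", "correlation")

_EPS = 1e-12


def chebyshev_distance(v_a: np.ndarray, v_b: np.ndarray) -> float:
    """Max absolute coordinate difference between two feature vectors."""
    v_a = np.asarray(v_a, dtype=float)
    v_b = np.asarray(v_b, dtype=float)
    if v_a.shape != v_b.shape:
        raise ValueError(f"length mismatch: {v_a.shape} vs {v_b.shape}")
    if not (np.all(np.isfinite(v_a)) and np.all(np.isfinite(v_b))):
        raise ValueError("non-finite values in feature vectors")
    if v_a.size == 0:
        return 0.0
    return float(np.max(np.abs(v_a - v_b)))


def similarity_from_features(
    F: FeatureMatrix, metric: str = "chebyshev"
) -> SimilarityView:
    """Pairwise similarity view from one feature matrix.

    Distances above 1 anywhere trigger min-max scaling of the whole
    distance matrix before the 1-D flip; the diagonal is forced to 1 and
    the zero-row mask is carried over from the source features.
    A constant feature matrix (all rows identical) is valid and yields the
    all-ones similarity.
    """
    if metric not in SUPPORTED_METRICS:
        raise ValueError(f"unsupported metric {metric!r}; one of {SUPPORTED_METRICS}")
    X = F.values
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to build a similarity view")
    D = cdist(X, X, metric=metric)
    D = np.nan_to_num(D, nan=0.0)  # e.g. cosine of zero rows
    d_max = D.max()
    if d_max > 1.0:
        D = D / max(d_max, _EPS)
    S = 1.0 - D
    S = (S + S.T) / 2.0
    S = np.clip(S, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return SimilarityView(
        index=F.index,
        view_name=F.view_name,
        S=S,
        zero_row_mask=F.zero_row_mask.copy(),
        metric=metric,
    )


def build_all_views(
    drug_features: Mapping[str, FeatureMatrix],
    cell_features: Mapping[str, FeatureMatrix],
    metric: str = "chebyshev",
) -> tuple[dict[str, SimilarityView], dict[str, FeatureMatrix | SimilarityView]]:
    """All 12 drug similarity views and the 4 cell feature views.

    Drug side: the six fingerprint views and the four association views are
    converted with the chosen metric; the combined-score view is already a
    similarity and passes through unchanged; the IC50-profile view (``dc_profile``)
    is converted like the others.  Cell side: only the cell IC50 profile
    (``cd_profile``) becomes a similarity (SM_CD); the three omics matrices
    stay raw feature views consumed directly by the model.
    """
    needed_drug = set(DRUG_VIEW_ORDER)
    missing = needed_drug - set(drug_features)
    if missing:
        raise ValueError(f"missing drug feature views: {sorted(missing)}")
    needed_cell = set(CELL_VIEW_ORDER)
    missing_c = needed_cell - set(cell_features)
    if missing_c:
        raise ValueError(f"missing cell feature views: {sorted(missing_c)}")

    drug_views: dict[str, SimilarityView] = {}
    for name in DRUG_VIEW_ORDER:
        F = drug_features[name]
        if name == "combined":
            # already a [0,1] similarity with unit diagonal: pass through
            drug_views[name] = SimilarityView(
                index=F.index,
                view_name=name,
                S=np.maximum(F.values, F.values.T),
                zero_row_mask=F.zero_row_mask.copy(),
                metric="identity",
            )
        else:
            drug_views[name] = similarity_from_features(F, metric=metric)

    cell_views: dict[str, FeatureMatrix | SimilarityView] = {
        "exp": cell_features["exp"],
        "mu": cell_features["mu"],
        "cnv": cell_features["cnv"],
        "cd_profile": similarity_from_features(cell_features["cd_profile"],
                                               metric=metric),
    }
    return drug_views, cell_views
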