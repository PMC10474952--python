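"""Core containers: entity indices, feature matrices, similarity views.

Every matrix in a run is row-aligned to an :class:`EntityIndex` (one for
drugs, one for cell lines).  Alignment is by position; the index is the
single source of truth for entity order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EntityIndex",
    "FeatureMatrix",
    "SimilarityView",
    "FusedSimilarity",
    "CompletedView",
    "SNFParams",
    "write_matrix_csv",
    "read_matrix_csv",
]

#: feature / similarity views recognised throughout the package
DRUG_FINGERPRINT_VIEWS = ("ECFP", "PSFP", "DFP", "RDKFP", "ESPFP", "ERGFP")
DRUG_ASSOCIATION_VIEWS = ("target", "disease", "miRNA", "ADR")
DRUG_VIEW_ORDER = (
    "combined",
    *DRUG_ASSOCIATION_VIEWS,
    *DRUG_FINGERPRINT_VIEWS,
    "dc_profile",
)
CELL_VIEW_ORDER = ("exp", "mu", "cnv", "cd_profile")


@dataclass(frozen=True)
class EntityIndex:
    """Ordered, unique identifiers for one role (drugs or cell lines)."""

    ids: tuple[str, ...]
    role: str  # "drug" | "cell"

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if list(self.ids).count(i) > 1})
            raise ValueError(f"duplicate entity ids: {dupes}")
        if self.role not in ("drug", "cell"):
            raise ValueError(f"role must be 'drug' or 'cell', got {self.role!r}")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def positions(self) -> dict[str, int]:
        return {e: i for i, e in enumerate(self.ids)}

    def position_of(self, entity_id: str) -> int:
        try:
            return self.positions[str(entity_id)]
        except KeyError:
            raise KeyError(
                f"unknown {self.role} id {entity_id!r} (not in EntityIndex)"
            ) from None


@dataclass
class FeatureMatrix:
    """One view's raw features; rows aligned to ``index``.

    ``value_range`` declares the contract per view: ``"binary"`` (entries in
    {0,1}), ``"unit"`` (entries in [0,1]) or ``"real"`` (unbounded).
    """

    index: EntityIndex
    view_name: str
    values: np.ndarray
    value_range: str = "real"
    zero_row_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape[0] != len(self.index):
            raise ValueError(
                f"view {self.view_name!r}: {self.values.shape[0]} rows but "
                f"{len(self.index)} entities in index"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"view {self.view_name!r}: non-finite values")
        if self.value_range == "binary":
            if not np.isin(self.values, (0.0, 1.0)).all():
                raise ValueError(
                    f"view {self.view_name!r} declared binary but has "
                    "entries outside {0,1}"
                )
        elif self.value_range == "unit":
            if self.values.min() < 0.0 or self.values.max() > 1.0:
                raise ValueError(
                    f"view {self.view_name!r} declared unit-range but has "
                    "entries outside [0,1]"
                )
        if self.zero_row_mask is None:
            self.zero_row_mask = ~self.values.any(axis=1)
        else:
            self.zero_row_mask = np.asarray(self.zero_row_mask, dtype=bool)
            if self.zero_row_mask.shape != (len(self.index),):
                raise ValueError("zero_row_mask length must match index")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class SimilarityView:
    """Square symmetric entity x entity similarity matrix in [0,1]."""

    index: EntityIndex
    view_name: str
    S: np.ndarray
    zero_row_mask: np.ndarray | None = None
    metric: str | None = None

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        n = len(self.index)
        if self.S.shape != (n, n):
            raise ValueError(
                f"similarity {self.view_name!r}: shape {self.S.shape} != ({n},{n})"
            )
        if not np.array_equal(self.S, self.S.T):
            raise ValueError(f"similarity {self.view_name!r} is not symmetric")
        if self.S.min() < 0.0 or self.S.max() > 1.0:
            raise ValueError(f"similarity {self.view_name!r} outside [0,1]")
        if not np.allclose(np.diag(self.S), 1.0):
            raise ValueError(f"similarity {self.view_name!r} diagonal != 1")
        if self.zero_row_mask is None:
            self.zero_row_mask = np.zeros(n, dtype=bool)
        else:
            self.zero_row_mask = np.asarray(self.zero_row_mask, dtype=bool)


@dataclass(frozen=True)
class SNFParams:
    """Similarity-network-fusion hyperparameters.

    k: neighbourhood size of the sparse kernel; t: diffusion rounds;
    mu: bandwidth scaling used when an affinity is built from distances.
    """

    k: int
    t: int = 20
    mu: float = 0.5


@dataclass
class FusedSimilarity:
    """SNF output over >=2 similarity views of the same entities."""

    index: EntityIndex
    S: np.ndarray
    source_views: tuple[str, ...]
    snf_params: SNFParams

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        n = len(self.index)
        if self.S.shape != (n, n):
            raise ValueError(f"fused matrix shape {self.S.shape} != ({n},{n})")
        if not np.all(np.isfinite(self.S)):
            raise ValueError("fused matrix has non-finite entries")
        if self.S.min() < 0:
            raise ValueError("fused matrix has negative entries")
        asym = np.abs(self.S - self.S.T).max()
        if asym > 1e-10:
            raise ValueError(f"fused matrix not symmetric (max asym {asym:g})")


@dataclass
class CompletedView:
    """A sparse similarity view after zero rows/columns were filled."""

    base: SimilarityView
    filled_entities: frozenset[str]

    @property
    def S(self) -> np.ndarray:
        return self.base.S

    @property
    def view_name(self) -> str:
        return self.base.view_name

    @property
    def index(self) -> EntityIndex:
        return self.base.index


# ---------------------------------------------------------------------------
# serialization: CSV matrix + JSON sidecar
# ---------------------------------------------------------------------------

def write_matrix_csv(
    path: str | Path,
    values: np.ndarray,
    row_ids: Sequence[str],
    col_ids: Sequence[str],
    sidecar: Mapping | None = None,
) -> None:
    """Write a matrix as CSV (ids as header / first column) + JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(np.asarray(values), index=list(row_ids), columns=list(col_ids))
    df.to_csv(path, index_label="id")
    if sidecar is not None:
        meta = dict(sidecar)
        meta.setdefault("shape", list(df.shape))
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(meta, indent=2, default=str)
        )


def read_matrix_csv(path: str | Path) -> tuple[np.ndarray, list[str], list[str], dict]:
    """Read a matrix written by :func:`write_matrix_csv`.

    Returns (values, row_ids, col_ids, sidecar-dict); the sidecar is empty
    if no ``.json`` file sits next to the CSV.
    """
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return (
        df.to_numpy(dtype=float),
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
        meta,
    )
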