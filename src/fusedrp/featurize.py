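"""Build the raw feature matrices for drugs and cell lines.

Drug side: six molecular-fingerprint matrices, four binary association
matrices (targets, diseases, miRNAs, adverse reactions), one drug-drug
combined-score matrix (STITCH-style scores in 1..1000, rescaled to [0,1])
and the IC50 interaction-profile matrix.  Cell side: three omics matrices
(expression, mutation, copy number) over a fixed gene panel and the
cell x drug IC50 profile matrix.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence

import numpy as np
import pandas as pd

from .entities import (
    DRUG_FINGERPRINT_VIEWS,
    EntityIndex,
    FeatureMatrix,
)

__all__ = [
    "AssociationTable",
    "build_association_matrix",
    "build_combined_score_matrix",
    "build_ic50_profile_matrices",
    "build_fingerprint_matrices",
    "FINGERPRINT_WIDTHS",
    "SyntheticFingerprintBackend",
    "RDKitFingerprintBackend",
]

#: published row widths of the six fingerprint families
FINGERPRINT_WIDTHS: dict[str, int] = {
    "ECFP": 1024,
    "PSFP": 881,
    "DFP": 2048,
    "RDKFP": 200,
    "ESPFP": 2586,
    "ERGFP": 315,
}

#: continuous [0,1] fingerprint views; the rest are bit vectors
CONTINUOUS_FINGERPRINTS = ("RDKFP", "ERGFP")


@dataclass
class AssociationTable:
    """Edge list between entities and a partner vocabulary.

    Duplicate edges collapse to one.  ``weights`` is None for plain
    association tables and a parallel list for weighted (combined-score)
    tables.
    """

    edges: list[tuple[str, str]]
    partner_vocabulary: tuple[str, ...]
    weights: list[float] | None = None

    def __post_init__(self) -> None:
        if not self.partner_vocabulary:
            raise ValueError("partner_vocabulary must be non-empty")
        self.partner_vocabulary = tuple(str(p) for p in self.partner_vocabulary)
        if self.weights is not None and len(self.weights) != len(self.edges):
            raise ValueError("weights must parallel edges")
        # collapse duplicates, keeping the last weight seen for an edge
        seen: dict[tuple[str, str], float | None] = {}
        for i, (a, b) in enumerate(self.edges):
            w = self.weights[i] if self.weights is not None else None
            seen[(str(a), str(b))] = w
        self.edges = list(seen.keys())
        self.weights = None if self.weights is None else [seen[e] for e in self.edges]


def build_association_matrix(
    table: AssociationTable, index: EntityIndex
) -> FeatureMatrix:
    """Binary entity x partner indicator matrix.

    Entry (i, j) is 1 iff edge (entity_i, partner_j) is present.  Entities
    with no edges yield all-zero rows; they are preserved and flagged in
    ``zero_row_mask`` so the similarity completion step can find them.
    """
    pos = index.positions
    vocab_pos = {p: j for j, p in enumerate(table.partner_vocabulary)}
    M = np.zeros((len(index), len(table.partner_vocabulary)))
    for ent, partner in table.edges:
        if ent not in pos:
            raise KeyError(f"unknown {index.role} id {ent!r} in association table")
        if partner not in vocab_pos:
            raise KeyError(f"partner {partner!r} not in partner_vocabulary")
        M[pos[ent], vocab_pos[partner]] = 1.0
    return FeatureMatrix(index=index, view_name="association", values=M,
                         value_range="binary")


def build_combined_score_matrix(
    table: AssociationTable, index: EntityIndex
) -> FeatureMatrix:
    """Drug x drug combined-score matrix, scores/1000 so entries lie in [0,1].

    Unknown pairs are 0; the matrix is symmetrized by the max of the two
    directions and the diagonal is set to 1 (self-similarity convention).
    The returned ``zero_row_mask`` flags drugs with no known score at all.
    """
    if table.weights is None:
        raise ValueError("combined-score table must carry weights")
    pos = index.positions
    n = len(index)
    M = np.zeros((n, n))
    for (a, b), w in zip(table.edges, table.weights):
        if a not in pos:
            raise KeyError(f"unknown drug id {a!r} in combined-score table")
        if b not in pos:
            raise KeyError(f"unknown drug id {b!r} in combined-score table")
        if w is None or not (1.0 <= w <= 1000.0):
            raise ValueError(
                f"combined score for ({a},{b}) must lie in [1,1000], got {w!r}"
            )
        M[pos[a], pos[b]] = w / 1000.0
    M = np.maximum(M, M.T)
    mask = ~M.any(axis=1)  # before the diagonal is forced
    np.fill_diagonal(M, 1.0)
    return FeatureMatrix(index=index, view_name="combined", values=M,
                         value_range="unit", zero_row_mask=mask)


def build_ic50_profile_matrices(
    triples: pd.DataFrame,
    drug_index: EntityIndex,
    cell_index: EntityIndex,
    fill_value: float = 0.0,
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Cell x drug IC50 matrix M_CD and its transpose M_DC.

    ``triples`` must have columns (drug_id, cell_id, ic50) and should be
    restricted to the training split by the caller — building profiles from
    validation/test responses would leak labels into the features.
    Unobserved pairs take ``fill_value`` (default 0).
    Duplicate (drug, cell) pairs with conflicting IC50 raise.
    """
    required = {"drug_id", "cell_id", "ic50"}
    if not required.issubset(triples.columns):
        raise ValueError(f"triples must have columns {sorted(required)}")
    dup = triples.groupby(["drug_id", "cell_id"])["ic50"].nunique()
    conflicts = dup[dup > 1]
    if len(conflicts):
        pair = conflicts.index[0]
        raise ValueError(f"conflicting IC50 values for pair {pair}")
    triples = triples.drop_duplicates(["drug_id", "cell_id"])

    m, n = len(cell_index), len(drug_index)
    M_CD = np.full((m, n), float(fill_value))
    dpos, cpos = drug_index.positions, cell_index.positions
    for row in triples.itertuples(index=False):
        d, c = str(row.drug_id), str(row.cell_id)
        if d not in dpos:
            raise KeyError(f"unknown drug id {d!r} in IC50 triples")
        if c not in cpos:
            raise KeyError(f"unknown cell id {c!r} in IC50 triples")
        M_CD[cpos[c], dpos[d]] = float(row.ic50)
    cd = FeatureMatrix(index=cell_index, view_name="cd_profile", values=M_CD)
    dc = FeatureMatrix(index=drug_index, view_name="dc_profile", values=M_CD.T.copy())
    return cd, dc


# ---------------------------------------------------------------------------
# fingerprints
# ---------------------------------------------------------------------------

class FingerprintBackend(Protocol):
    def __call__(self, smiles: Sequence[str]) -> dict[str, np.ndarray]: ...


def _hash_bits(key: str, width: int) -> np.ndarray:
    """Deterministic pseudo-fingerprint: bits seeded from a string digest."""
    digest = hashlib.sha256(key.encode()).digest()
    seed = int.from_bytes(digest[:4], "little")
    rng = np.random.default_rng(seed)
    return (rng.random(width) < 0.25).astype(float)


class SyntheticFingerprintBackend:
    """Deterministic bitstring fingerprints keyed on the SMILES text.

    Identical SMILES map to identical rows in every view; no cheminformatics
    dependency.  Intended for fixtures and tests.
    """

    def __call__(self, smiles: Sequence[str]) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for view, width in FINGERPRINT_WIDTHS.items():
            rows = [_hash_bits(f"{view}|{s}", width) for s in smiles]
            M = np.stack(rows)
            if view in CONTINUOUS_FINGERPRINTS:
                # graded [0,1] values instead of bits for the continuous view
                M = np.stack(
                    [_continuous_row(f"{view}|{s}", width) for s in smiles]
                )
            out[view] = M
        return out


def _continuous_row(key: str, width: int) -> np.ndarray:
    digest = hashlib.sha256(key.encode()).digest()
    rng = np.random.default_rng(int.from_bytes(digest[4:8], "little"))
    return rng.random(width)


class RDKitFingerprintBackend:
    """Fingerprints computed with RDKit where the family is available.

    ECFP (Morgan radius 2, 1024 bits), DFP (RDKit topological, 2048 bits)
    and ERGFP (ErG, 315-dim) are the genuine articles.  PSFP and ESPFP have
    no implementation in this stack and are emitted as deterministic hashed
    structural fingerprints of the canonical SMILES at the published widths;
    RDKFP is a min-max-normalized panel of 200 RDKit 2D descriptors.
    """

    def __call__(self, smiles: Sequence[str]) -> dict[str, np.ndarray]:
        from rdkit import Chem  # lazy: optional dependency
        from rdkit.Chem import AllChem, Descriptors
        from rdkit.Chem.rdReducedGraphs import GetErGFingerprint

        mols = []
        for s in smiles:
            mol = Chem.MolFromSmiles(s)
            if mol is None:
                raise ValueError(f"unparseable SMILES: {s!r}")
            mols.append(mol)
        canon = [Chem.MolToSmiles(m) for m in mols]

        ecfp = np.array(
            [list(AllChem.GetMorganFingerprintAsBitVect(m, 2, nBits=1024))
             for m in mols], dtype=float)
        dfp = np.array(
            [list(Chem.RDKFingerprint(m, fpSize=2048)) for m in mols],
            dtype=float)
        erg = np.stack([np.asarray(GetErGFingerprint(m), dtype=float)
                        for m in mols])
        erg = np.clip(erg, 0.0, None)
        if erg.max() > 0:
            erg = erg / erg.max()

        desc_fns = Descriptors.descList[: FINGERPRINT_WIDTHS["RDKFP"]]
        raw = np.array([[fn(m) for _, fn in desc_fns] for m in mols], dtype=float)
        raw = np.nan_to_num(raw, nan=0.0, posinf=0.0, neginf=0.0)
        lo, hi = raw.min(axis=0), raw.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        rdkfp = (raw - lo) / span
        if rdkfp.shape[1] < FINGERPRINT_WIDTHS["RDKFP"]:
            pad = FINGERPRINT_WIDTHS["RDKFP"] - rdkfp.shape[1]
            rdkfp = np.pad(rdkfp, ((0, 0), (0, pad)))

        psfp = np.stack([_hash_bits(f"PSFP|{s}", FINGERPRINT_WIDTHS["PSFP"])
                         for s in canon])
        espfp = np.stack([_hash_bits(f"ESPFP|{s}", FINGERPRINT_WIDTHS["ESPFP"])
                          for s in canon])
        return {"ECFP": ecfp, "PSFP": psfp, "DFP": dfp, "RDKFP": rdkfp,
                "ESPFP": espfp, "ERGFP": erg}


def build_fingerprint_matrices(
    index: EntityIndex,
    smiles: Sequence[str] | None = None,
    precomputed: Mapping[str, np.ndarray] | None = None,
    backend: FingerprintBackend | None = None,
) -> dict[str, FeatureMatrix]:
    """Six fingerprint FeatureMatrices, from SMILES or precomputed arrays.

    Precomputed matrices are validated against the published column widths
    (1024, 881, 2048, 200, 2586, 315).  When computing from SMILES the
    backend defaults to :class:`SyntheticFingerprintBackend`.
    """
    if (smiles is None) == (precomputed is None):
        raise ValueError("provide exactly one of smiles or precomputed")
    if precomputed is None:
        assert smiles is not None
        if len(smiles) != len(index):
            raise ValueError("one SMILES per drug required")
        backend = backend or SyntheticFingerprintBackend()
        precomputed = backend(smiles)

    missing = set(DRUG_FINGERPRINT_VIEWS) - set(precomputed)
    if missing:
        raise ValueError(f"missing fingerprint views: {sorted(missing)}")

    out: dict[str, FeatureMatrix] = {}
    for view in DRUG_FINGERPRINT_VIEWS:
        M = np.asarray(precomputed[view], dtype=float)
        width = FINGERPRINT_WIDTHS[view]
        if M.shape != (len(index), width):
            raise ValueError(
                f"fingerprint {view}: expected shape {(len(index), width)}, "
                f"got {M.shape}"
            )
        vr = "unit" if view in CONTINUOUS_FINGERPRINTS else "binary"
        out[view] = FeatureMatrix(index=index, view_name=view, values=M,
                                  value_range=vr)
    return out
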