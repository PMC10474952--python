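"""Synthetic benchmark generator with a planted, recoverable signal.

Drugs and cell lines get latent vectors u_i, w_j; the response surface is
bilinear, IC50(i, j) = u_i^T A w_j + b + eps, with the noiseless signal
standardized to unit variance so ``noise_sd`` reads directly as a fraction
of the signal scale.  Every input the real pipeline consumes is emulated:

* fingerprints: thresholded (binary views) or squashed (continuous view)
  random projections of u_i, so similar latents give similar fingerprints;
* association tables: edges sampled with probability increasing in the
  latent affinity to per-partner anchors; a configurable fraction of drugs
  is forced edgeless per view (the zero rows the completion step fills);
* combined scores: 1..1000 scores from latent affinity, on a random subset
  of drug pairs;
* omics: linear read-outs of w_j plus Gaussian noise;
* IC50 triples over a random subset of the drug x cell grid.

The generator emulates the *structure* of a drug-response benchmark, not
real pharmacology; see docs/methods.md for what that implies about tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .entities import EntityIndex, FeatureMatrix
from .featurize import FINGERPRINT_WIDTHS, AssociationTable

__all__ = ["SyntheticConfig", "SyntheticBundle", "generate",
           "planted_signal_check", "write_bundle", "read_bundle"]

_ASSOC_VIEWS = {"target": 40, "disease": 50, "miRNA": 30, "ADR": 45}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic benchmark."""

    n_drugs: int = 30
    m_cells: int = 40
    latent_dim: int = 4
    n_genes: int = 60
    noise_sd: float = 0.1          # fraction of (unit) signal sd
    zero_row_fraction: float = 0.1  # edgeless drugs per association view
    pair_fraction: float = 0.85     # observed cells of the drug x cell grid
    combined_density: float = 0.5   # drug pairs with a known combined score
    omics_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_drugs, self.m_cells, self.latent_dim) < 3:
            raise ValueError("all counts must be >= 3")
        if not (0.0 <= self.zero_row_fraction <= 0.5):
            raise ValueError("zero_row_fraction must lie in [0, 0.5]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 < self.pair_fraction <= 1.0):
            raise ValueError("pair_fraction must lie in (0, 1]")


@dataclass
class SyntheticBundle:
    """Everything the pipeline consumes, plus the generating latents."""

    config: SyntheticConfig
    drug_index: EntityIndex
    cell_index: EntityIndex
    smiles: list[str]
    fingerprints: dict[str, np.ndarray]
    association_tables: dict[str, AssociationTable]
    combined_table: AssociationTable
    omics: dict[str, FeatureMatrix]
    pairs: pd.DataFrame  # columns drug_id, cell_id, ic50
    drug_latents: np.ndarray
    cell_latents: np.ndarray
    bilinear_core: np.ndarray


def _latent_affinity(U: np.ndarray) -> np.ndarray:
    """Cosine affinity in [0,1] between latent rows."""
    norms = np.linalg.norm(U, axis=1, keepdims=True)
    norms = np.where(norms > 0, norms, 1.0)
    C = (U / norms) @ (U / norms).T
    return (C + 1.0) / 2.0


def generate(cfg: SyntheticConfig) -> SyntheticBundle:
    rng = np.random.default_rng(cfg.seed)
    n, m, d = cfg.n_drugs, cfg.m_cells, cfg.latent_dim
    drug_ids = [f"D{i:03d}" for i in range(n)]
    cell_ids = [f"C{j:03d}" for j in range(m)]
    drug_index = EntityIndex(tuple(drug_ids), "drug")
    cell_index = EntityIndex(tuple(cell_ids), "cell")

    U = rng.normal(size=(n, d))
    W = rng.normal(size=(m, d))
    A = rng.normal(size=(d, d)) / np.sqrt(d)
    Z = U @ A @ W.T
    Z = (Z - Z.mean()) / Z.std()  # unit-variance signal
    noise = rng.normal(scale=cfg.noise_sd, size=(n, m)) if cfg.noise_sd else 0.0
    IC = Z + noise

    # synthetic SMILES: latent-derived token strings, unique per drug
    smiles = ["".join("CNOS"[t] for t in
                      (np.abs(np.floor(U[i] * 7)).astype(int) % 4)) + f"#{i}"
              for i in range(n)]

    # fingerprints: random projections of the latents
    fingerprints: dict[str, np.ndarray] = {}
    for view, width in FINGERPRINT_WIDTHS.items():
        R = rng.normal(size=(d, width))
        proj = U @ R
        if view == "RDKFP":
            fingerprints[view] = 1.0 / (1.0 + np.exp(-proj))  # graded [0,1]
        else:
            fingerprints[view] = (proj > 0).astype(float)

    # association tables with planted zero-row drugs
    n_zero = int(np.floor(cfg.zero_row_fraction * n))
    association_tables: dict[str, AssociationTable] = {}
    for view, n_partners in _ASSOC_VIEWS.items():
        partners = tuple(f"{view}_{p}" for p in range(n_partners))
        anchors = rng.normal(size=(n_partners, d))
        logits = U @ anchors.T / np.sqrt(d)
        prob = 1.0 / (1.0 + np.exp(-(logits - 0.5)))
        hits = rng.random((n, n_partners)) < prob
        zero_rows = rng.choice(n, size=n_zero, replace=False)
        hits[zero_rows] = False
        # drugs outside the planted zero set keep at least one edge
        for i in range(n):
            if i not in zero_rows and not hits[i].any():
                hits[i, rng.integers(n_partners)] = True
        edges = [(drug_ids[i], partners[j]) for i, j in zip(*np.nonzero(hits))]
        association_tables[view] = AssociationTable(
            edges=edges, partner_vocabulary=partners)

    # combined scores on a random subset of pairs, scaled latent affinity
    aff = _latent_affinity(U)
    combined_edges, combined_weights = [], []
    zero_rows_combined = set(rng.choice(n, size=n_zero, replace=False).tolist())
    for i in range(n):
        for j in range(i + 1, n):
            if i in zero_rows_combined or j in zero_rows_combined:
                continue
            if rng.random() < cfg.combined_density:
                combined_edges.append((drug_ids[i], drug_ids[j]))
                combined_weights.append(
                    float(np.clip(round(1000 * aff[i, j]), 1, 1000)))
    combined_table = AssociationTable(
        edges=combined_edges,
        partner_vocabulary=tuple(drug_ids),
        weights=combined_weights,
    )

    # omics: linear read-outs of the cell latents plus noise
    omics: dict[str, FeatureMatrix] = {}
    for view in ("exp", "mu", "cnv"):
        B = rng.normal(size=(d, cfg.n_genes))
        M = W @ B + rng.normal(scale=cfg.omics_noise_sd, size=(m, cfg.n_genes))
        omics[view] = FeatureMatrix(index=cell_index, view_name=view, values=M)

    # observed IC50 triples
    grid = [(i, j) for i in range(n) for j in range(m)]
    n_obs = int(round(cfg.pair_fraction * len(grid)))
    chosen = rng.choice(len(grid), size=n_obs, replace=False)
    rows = [(drug_ids[grid[k][0]], cell_ids[grid[k][1]], IC[grid[k][0], grid[k][1]])
            for k in sorted(chosen)]
    pairs = pd.DataFrame(rows, columns=["drug_id", "cell_id", "ic50"])

    return SyntheticBundle(
        config=cfg,
        drug_index=drug_index,
        cell_index=cell_index,
        smiles=smiles,
        fingerprints=fingerprints,
        association_tables=association_tables,
        combined_table=combined_table,
        omics=omics,
        pairs=pairs,
        drug_latents=U,
        cell_latents=W,
        bilinear_core=A,
    )


def planted_signal_check(
    bundle: SyntheticBundle,
    train_fraction: float = 0.8,
    seed: int = 0,
    ridge: float = 1e-6,
) -> float:
    """Held-out Pearson r of the bilinear oracle fit on the true latents.

    Regresses IC50 on the flattened outer products u_i (x) w_j (plus
    intercept) by ridge least squares — the ceiling a model could reach by
    recovering the planted signal exactly.  Returns held-out r.
    """
    U, W = bundle.drug_latents, bundle.cell_latents
    pairs = bundle.pairs
    dpos = bundle.drug_index.positions
    cpos = bundle.cell_index.positions
    di = pairs["drug_id"].map(dpos).to_numpy()
    cj = pairs["cell_id"].map(cpos).to_numpy()
    X = np.einsum("np,nq->npq", U[di], W[cj]).reshape(len(pairs), -1)
    X = np.column_stack([X, np.ones(len(pairs))])
    y = pairs["ic50"].to_numpy()

    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pairs))
    cut = int(round(train_fraction * len(pairs)))
    tr, te = perm[:cut], perm[cut:]
    XtX = X[tr].T @ X[tr] + ridge * np.eye(X.shape[1])
    beta = np.linalg.solve(XtX, X[tr].T @ y[tr])
    pred = X[te] @ beta
    if np.std(pred) == 0 or np.std(y[te]) == 0:
        return 0.0
    return float(stats.pearsonr(pred, y[te])[0])


# ---------------------------------------------------------------------------
# on-disk fixture dialect (the same CSVs the pipeline reads)
# ---------------------------------------------------------------------------

def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> None:
    """Write the bundle in the pipeline's plain-text input formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"drug_id": bundle.drug_index.ids,
                  "smiles": bundle.smiles}).to_csv(
        out / "drugs.tsv", sep="\t", index=False)
    for view, M in bundle.fingerprints.items():
        df = pd.DataFrame(M, index=list(bundle.drug_index.ids))
        df.to_csv(out / f"fingerprint_{view}.csv", index_label="drug_id")
    for view, table in bundle.association_tables.items():
        pd.DataFrame(table.edges, columns=["drug_id", "partner_id"]).to_csv(
            out / f"assoc_{view}.csv", index=False)
        (out / f"assoc_{view}.vocab.txt").write_text(
            "\n".join(table.partner_vocabulary) + "\n")
    pd.DataFrame(
        [(a, b, w) for (a, b), w in
         zip(bundle.combined_table.edges, bundle.combined_table.weights)],
        columns=["drug_id", "partner_id", "score"],
    ).to_csv(out / "combined_scores.csv", index=False)
    for view, fm in bundle.omics.items():
        pd.DataFrame(fm.values, index=list(bundle.cell_index.ids)).to_csv(
            out / f"omics_{view}.csv", index_label="cell_id")
    bundle.pairs.to_csv(out / "pairs.csv", index=False)


def read_input_bundle(in_dir: str | Path) -> SyntheticBundle:
    """Load a bundle directory written by :func:`write_bundle`.

    Returns a :class:`SyntheticBundle` whose latent fields are zero arrays:
    user-supplied data has no planted signal, only the pipeline inputs.
    """
    d = Path(in_dir)
    drugs = pd.read_csv(d / "drugs.tsv", sep="\t", dtype=str)
    drug_index = EntityIndex(tuple(drugs["drug_id"]), "drug")
    smiles = list(drugs["smiles"])

    fingerprints = {}
    for f in sorted(d.glob("fingerprint_*.csv")):
        view = f.stem.split("_", 1)[1]
        fingerprints[view] = pd.read_csv(f, index_col=0).to_numpy(dtype=float)

    association_tables = {}
    for f in sorted(d.glob("assoc_*.csv")):
        view = f.stem.split("_", 1)[1]
        edges_df = pd.read_csv(f, dtype=str)
        vocab = tuple((d / f"assoc_{view}.vocab.txt").read_text().split())
        association_tables[view] = AssociationTable(
            edges=list(edges_df.itertuples(index=False, name=None)),
            partner_vocabulary=vocab)

    cs = pd.read_csv(d / "combined_scores.csv", dtype={"drug_id": str,
                                                       "partner_id": str})
    combined_table = AssociationTable(
        edges=list(zip(cs["drug_id"], cs["partner_id"])),
        partner_vocabulary=tuple(drug_index.ids),
        weights=[float(w) for w in cs["score"]])

    omics = {}
    cell_index = None
    for view in ("exp", "mu", "cnv"):
        df = pd.read_csv(d / f"omics_{view}.csv", index_col=0)
        if cell_index is None:
            cell_index = EntityIndex(tuple(str(i) for i in df.index), "cell")
        omics[view] = FeatureMatrix(index=cell_index, view_name=view,
                                    values=df.to_numpy(dtype=float))

    pairs = pd.read_csv(d / "pairs.csv",
                        dtype={"drug_id": str, "cell_id": str})
    n, m, k = len(drug_index), len(cell_index), 1
    return SyntheticBundle(
        config=SyntheticConfig(n_drugs=max(n, 3), m_cells=max(m, 3)),
        drug_index=drug_index, cell_index=cell_index, smiles=smiles,
        fingerprints=fingerprints, association_tables=association_tables,
        combined_table=combined_table, omics=omics, pairs=pairs,
        drug_latents=np.zeros((n, k)), cell_latents=np.zeros((m, k)),
        bilinear_core=np.zeros((k, k)))


def read_bundle_matrices(in_dir: str | Path) -> dict[str, np.ndarray]:
    """Read back the numeric fixture matrices (round-trip checks)."""
    out: dict[str, np.ndarray] = {}
    for f in sorted(Path(in_dir).glob("*.csv")):
        if f.name in ("pairs.csv", "combined_scores.csv") or \
                f.name.startswith("assoc_"):
            continue
        out[f.stem] = pd.read_csv(f, index_col=0).to_numpy(dtype=float)
    return out


read_bundle = read_bundle_matrices
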