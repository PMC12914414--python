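"""Single-cell quality control: per-cell metrics, filtering, doublet scoring.

The filter reproduces the standard droplet QC rule used for the merged
scRNA-seq libraries: keep cells with mitochondrial percentage strictly below
10% and more than 200 detected genes. Doublet scoring follows the
simulated-doublet kNN-density family: artificial doublets are synthesised by
summing random cell pairs, observed and simulated cells are embedded in a
shared PCA space of log-normalised expression, and each observed cell is
scored by the fraction of its neighbours that are simulated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io import CountMatrix


def compute_qc(m: CountMatrix, mito_prefix: str = "MT-") -> pd.DataFrame:
    """Per-cell totals, detected genes and mitochondrial percentage.

    Cells with zero total counts get ``mito_pct = 0`` and ``flagged = True``.
    """
    if m.n_genes == 0 or m.n_units == 0:
        raise ValueError("empty count matrix")
    is_mito = np.asarray([str(g).startswith(mito_prefix) for g in m.gene_ids])
    total = m.values.sum(axis=0)
    n_det = (m.values > 0).sum(axis=0)
    mito = m.values[is_mito].sum(axis=0) if is_mito.any() else np.zeros(m.n_units)
    with np.errstate(divide="ignore", invalid="ignore"):
        mito_pct = np.where(total > 0, 100.0 * mito / np.maximum(total, 1), 0.0)
    return pd.DataFrame({
        "total_counts": total,
        "n_genes_detected": n_det,
        "mito_pct": mito_pct,
        "flagged": total == 0,
    }, index=pd.Index(m.unit_ids, name="cell_id"))


def filter_cells(qc: pd.DataFrame, mito_max_pct: float = 10.0,
                 min_genes: int = 200) -> list:
    """Cell ids kept under ``mito_pct < mito_max_pct`` and
    ``n_genes_detected > min_genes`` (both strict, matching the
    "less than 10% / higher than 200" rule)."""
    if not 0 <= mito_max_pct <= 100:
        raise ValueError(f"mito_max_pct = {mito_max_pct} outside [0, 100]")
    if min_genes < 0:
        raise ValueError(f"min_genes must be >= 0, got {min_genes}")
    keep = (qc["mito_pct"] < mito_max_pct) & (qc["n_genes_detected"] > min_genes)
    return list(qc.index[keep])


def _log1p_cp10k(values: np.ndarray) -> np.ndarray:
    total = values.sum(axis=0).astype(float)
    total[total == 0] = 1.0
    return np.log1p(values / total * 1e4)


def doublet_score(m: CountMatrix, k: int = 30, n_sim_ratio: float = 1.0,
                  n_pcs: int = 20, seed: int = 0) -> pd.Series:
    """Simulated-doublet kNN density score per cell.

    ``ceil(n_sim_ratio * n_cells)`` artificial doublets (random pair sums)
    are co-embedded with the observed cells in the top ``n_pcs`` principal
    components of log1p counts-per-10k expression. The raw score — the
    fraction of a cell's ``k`` nearest neighbours that are simulated — is
    rescaled by the simulated:observed ratio so that the expected background
    is comparable across ratios.
    """
    n_cells = m.n_units
    if n_cells < 2 * k:
        raise ValueError(f"need at least {2 * k} cells for k={k}, got {n_cells}")
    rng = np.random.default_rng(seed)
    n_sim = int(np.ceil(n_sim_ratio * n_cells))
    pairs = rng.integers(0, n_cells, size=(n_sim, 2))
    sim = m.values[:, pairs[:, 0]] + m.values[:, pairs[:, 1]]

    x = _log1p_cp10k(np.concatenate([m.values, sim], axis=1)).T  # units × genes
    n_pcs = min(n_pcs, min(x.shape) - 1)
    emb = PCA(n_components=n_pcs, svd_solver="randomized",
              random_state=seed).fit_transform(x - x.mean(axis=0))

    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    _, idx = nn.kneighbors(emb[:n_cells])
    # drop the query cell itself by index (ties at distance 0 can reorder it)
    raw = np.empty(n_cells)
    for i in range(n_cells):
        neigh = idx[i][idx[i] != i][:k]
        raw[i] = np.mean(neigh >= n_cells)
    ratio = n_sim / n_cells
    score = raw / ratio if ratio > 0 else raw
    return pd.Series(score, index=pd.Index(m.unit_ids, name="cell_id"),
                     name="doublet_score")
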