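"""Pseudotime trajectories and pseudotime differential expression.

Pseudotime is a deterministic graph ordering: cells are embedded in the top
principal components of log-normalised expression, joined in a kNN graph
with Euclidean edge weights, and ordered by shortest-path distance from the
cell nearest the root population's centroid, min-max rescaled to [0, 1]
within each library. Pseudotime DE is a likelihood-ratio test of a
natural-cubic-spline Poisson regression of counts on pseudotime (log total
counts as offset) against the offset-only null, with p from chi2(df); a
gene is called significant when p < 0.001 and it is expressed in at least
10% of cells. Binned profiles (100 bins for heatmaps, 5 for bulk-PCA
projection) use contiguous equal-cell-count bins, and per-gene Pearson
correlation of binned profiles compares direct versus trans-differentiation
trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse
import scipy.sparse.csgraph
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors, kneighbors_graph

from .io import CountMatrix
from .signatures import ScaledMatrix


@dataclass
class PseudotimeAssignment:
    t: pd.Series                     # cell_id -> t in [0, 1]
    root_cell: str
    disconnected: list               # cells placed by nearest-connected fallback
    method: dict = field(default_factory=dict)


@dataclass
class BinnedProfile:
    condition: str
    n_bins: int
    means: pd.DataFrame              # genes × bins
    occupancy: np.ndarray            # cells per bin
    bin_t: np.ndarray                # mean pseudotime per bin


def _log1p_cp10k(values: np.ndarray) -> np.ndarray:
    total = values.sum(axis=0).astype(float)
    total[total == 0] = 1.0
    return np.log1p(values / total * 1e4)


def infer_pseudotime(m: CountMatrix, root_label: str,
                     labels: "pd.Series | None" = None, n_pcs: int = 20,
                     k: int = 15, smooth_passes: int = 2,
                     seed: int = 0) -> PseudotimeAssignment:
    """Shortest-path pseudotime from the root population, rescaled per library.

    Raw shortest-path distances accumulate independent per-hop noise, so
    after Dijkstra the distances are smoothed by ``smooth_passes`` rounds of
    kNN-neighbourhood averaging (self included) before the per-library
    min-max rescale; the ordering stays deterministic.
    """
    if labels is None:
        if "library" not in m.unit_meta.columns:
            raise ValueError("no library labels: pass `labels` or set unit_meta")
        labels = m.unit_meta["library"]
    labels = labels.loc[list(m.unit_ids)]
    if m.n_units < k + 1:
        raise ValueError(f"need at least {k + 1} cells for k={k}")
    root_mask = (labels == root_label).to_numpy()
    if not root_mask.any():
        raise ValueError(f"no cells labelled {root_label!r}")

    x = _log1p_cp10k(m.values).T
    n_pcs = min(n_pcs, min(x.shape) - 1)
    emb = PCA(n_components=n_pcs, svd_solver="randomized",
              random_state=seed).fit_transform(x - x.mean(axis=0))

    centroid = emb[root_mask].mean(axis=0)
    root_idx = int(np.argmin(np.linalg.norm(emb - centroid, axis=1)
                             + np.where(root_mask, 0.0, np.inf)))

    graph = kneighbors_graph(emb, n_neighbors=k, mode="distance")
    graph = graph.maximum(graph.T)  # symmetric undirected
    dist = scipy.sparse.csgraph.dijkstra(graph, directed=False, indices=root_idx)

    disconnected = []
    if np.isinf(dist).any():
        max_edge = graph.data.max() if graph.nnz else 1.0
        bad = np.where(np.isinf(dist))[0]
        good = np.where(np.isfinite(dist))[0]
        nn = NearestNeighbors(n_neighbors=1).fit(emb[good])
        _, j = nn.kneighbors(emb[bad])
        dist[bad] = dist[good[j[:, 0]]] + max_edge
        disconnected = [m.unit_ids[i] for i in bad]

    if smooth_passes > 0:
        # each cell's own kNN (plus itself): duplicated cells share the same
        # neighbourhood, keeping their smoothed distances identical
        conn = kneighbors_graph(emb, n_neighbors=k, mode="connectivity")
        conn = conn + scipy.sparse.eye(len(dist), format="csr")
        row_sums = np.asarray(conn.sum(axis=1)).ravel()
        for _ in range(smooth_passes):
            dist = conn.dot(dist) / row_sums

    t = pd.Series(dist, index=pd.Index(m.unit_ids, name="cell_id"), name="t")
    for lib in labels.unique():
        mask = (labels == lib).to_numpy()
        lo, hi = t[mask].min(), t[mask].max()
        t[mask] = (t[mask] - lo) / (hi - lo) if hi > lo else 0.0
    return PseudotimeAssignment(
        t, str(m.unit_ids[root_idx]), disconnected,
        {"root_label": root_label, "n_pcs": n_pcs, "k": k, "seed": seed},
    )


# ---------------------------------------------------------------------------
# natural cubic spline Poisson LRT


def natural_spline_basis(x: np.ndarray, df: int = 3) -> np.ndarray:
    """Natural-cubic-spline basis (no intercept column) with ``df`` columns.

    Boundary knots at min/max of ``x``, ``df - 1`` internal knots at
    quantiles — the conventional regression-spline construction.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    x = np.asarray(x, dtype=float)
    if df == 1:
        return x[:, None]
    probs = np.linspace(0, 1, df + 1)
    knots = np.quantile(x, probs)
    knots = np.unique(knots)
    if len(knots) < 3:  # degenerate x: fall back to a linear column + zeros
        out = np.zeros((len(x), df))
        out[:, 0] = x
        return out
    kk = knots[-1]

    def d(j):
        return (np.clip(x - knots[j], 0, None) ** 3
                - np.clip(x - kk, 0, None) ** 3) / (kk - knots[j])

    cols = [x]
    last = d(len(knots) - 2)
    for j in range(len(knots) - 2):
        cols.append(d(j) - last)
    basis = np.column_stack(cols[:df])
    while basis.shape[1] < df:
        basis = np.column_stack([basis, np.zeros(len(x))])
    return basis


def _poisson_lrt(y: np.ndarray, design: np.ndarray, offset: np.ndarray,
                 n_iter: int = 25) -> np.ndarray:
    """Batched Poisson IRLS LRT statistics, one per gene (rows of ``y``)."""
    n = design.shape[0]
    x = np.column_stack([np.ones(n), design])
    p = x.shape[1]
    g = y.shape[0]

    tot = y.sum(axis=1)
    off_exp = np.exp(offset)
    beta0 = np.log(np.maximum(tot, 1e-12) / off_exp.sum())
    ll_null = (y * (offset + beta0[:, None])).sum(axis=1) - tot  # e^{o+b0} sums to tot

    beta = np.zeros((g, p))
    beta[:, 0] = beta0
    ridge = 1e-10 * np.eye(p)
    for _ in range(n_iter):
        eta = np.clip(offset + beta @ x.T, -30.0, 30.0)
        mu = np.exp(eta)
        z = (eta - offset) + (y - mu) / mu
        xtwx = np.einsum("ni,gn,nj->gij", x, mu, x, optimize=True) + ridge
        xtwz = np.einsum("ni,gn->gi", x, mu * z, optimize=True)
        beta = np.linalg.solve(xtwx, xtwz[..., None])[..., 0]
    eta = np.clip(offset + beta @ x.T, -30.0, 30.0)
    ll_full = (y * eta).sum(axis=1) - np.exp(eta).sum(axis=1)
    return np.maximum(2.0 * (ll_full - ll_null), 0.0)


def pseudotime_de(m: CountMatrix, pt: PseudotimeAssignment,
                  min_frac: float = 0.10, alpha: float = 0.001,
                  df: int = 3) -> pd.DataFrame:
    """Spline Poisson LRT of expression on pseudotime, per gene.

    Genes expressed in fewer than ``min_frac`` of cells are excluded (NA
    p-values, never significant). Returns a table with
    ``fraction_expressing``, ``p``, ``padj`` and a ``significant`` flag at
    ``p < alpha``.
    """
    t = pt.t.loc[list(m.unit_ids)].to_numpy()
    n = len(t)
    if n < 10 * df:
        raise ValueError(f"need at least {10 * df} cells for df={df}, got {n}")
    y = m.values.astype(float)
    frac = (y > 0).mean(axis=1)
    keep = frac >= min_frac

    total = y.sum(axis=0)
    offset = np.log(np.maximum(total, 1.0))
    design = natural_spline_basis(t, df=df)

    p = np.full(m.n_genes, np.nan)
    if keep.any():
        lrt = _poisson_lrt(y[keep], design, offset)
        p[keep] = stats.chi2.sf(lrt, df=design.shape[1])

    from .de import adjust_bh

    out = pd.DataFrame({
        "gene_id": list(m.gene_ids),
        "fraction_expressing": frac,
        "p": p,
        "padj": adjust_bh(p),
    })
    out["significant"] = (out["p"] < alpha) & keep
    out.attrs["alpha"] = alpha
    out.attrs["min_frac"] = min_frac
    return out


# ---------------------------------------------------------------------------
# binning and cross-condition comparison


def bin_along_pseudotime(scaled, pt: PseudotimeAssignment, n_bins: int,
                         scheme: str = "equal_count",
                         condition: str = "") -> BinnedProfile:
    """Average expression per gene in ``n_bins`` pseudotime bins.

    ``equal_count`` (default) sorts cells by (t, cell id) and cuts them into
    contiguous bins of equal cell count, earlier bins taking the remainder;
    ``equal_width`` cuts [0, 1] into equal t-intervals and requires every
    bin to be occupied. ``scaled`` may be a :class:`ScaledMatrix` or any
    genes × units DataFrame (e.g. binned log-normalised expression for PCA
    projection).
    """
    if isinstance(scaled, ScaledMatrix):
        frame = scaled.as_frame()
    else:
        frame = scaled
    cells = [c for c in frame.columns if c in pt.t.index]
    if len(cells) < n_bins:
        raise ValueError(f"only {len(cells)} cells for {n_bins} bins")
    t = pt.t.loc[cells]
    order = sorted(range(len(cells)), key=lambda i: (t.iloc[i], cells[i]))
    cells = [cells[i] for i in order]
    tv = t.to_numpy()[order]

    if scheme == "equal_count":
        splits = np.array_split(np.arange(len(cells)), n_bins)
    elif scheme == "equal_width":
        edges = np.linspace(tv[0], tv[-1], n_bins + 1)
        which = np.clip(np.searchsorted(edges, tv, side="right") - 1, 0, n_bins - 1)
        splits = [np.where(which == b)[0] for b in range(n_bins)]
        if any(len(s) == 0 for s in splits):
            empty = [b for b, s in enumerate(splits) if len(s) == 0]
            raise ValueError(f"equal-width bins {empty} are empty")
    else:
        raise ValueError(f"unknown binning scheme {scheme!r}")

    vals = frame[cells].to_numpy()
    means = np.column_stack([vals[:, s].mean(axis=1) for s in splits])
    return BinnedProfile(
        condition, n_bins,
        pd.DataFrame(means, index=frame.index,
                     columns=[f"bin{b + 1}" for b in range(n_bins)]),
        np.asarray([len(s) for s in splits]),
        np.asarray([tv[s].mean() for s in splits]),
    )


def cross_condition_correlation(bin_a: BinnedProfile, bin_b: BinnedProfile,
                                genes: "list | None" = None) -> pd.Series:
    """Per-gene Pearson r between two binned trajectories, ranked descending.

    Genes with zero variance in either profile get ``r = NA`` (placed last).
    """
    if bin_a.n_bins != bin_b.n_bins:
        raise ValueError("profiles have different bin counts")
    if bin_a.n_bins < 3:
        raise ValueError("need at least 3 bins for a correlation")
    if genes is None:
        genes = bin_a.means.index.intersection(bin_b.means.index)
    a = bin_a.means.loc[genes].to_numpy()
    b = bin_b.means.loc[genes].to_numpy()
    a_c = a - a.mean(axis=1, keepdims=True)
    b_c = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt((a_c**2).sum(axis=1))
    sb = np.sqrt((b_c**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (a_c * b_c).sum(axis=1) / (sa * sb)
    r = np.where((sa == 0) | (sb == 0), np.nan, r)
    out = pd.Series(r, index=pd.Index(genes, name="gene_id"), name="pearson_r")
    return out.sort_values(ascending=False, na_position="last", kind="stable")


def group_by_significance(de_a: pd.DataFrame, de_b: pd.DataFrame) -> pd.DataFrame:
    """Partition genes by their significance in two pseudotime DE results.

    ``direct_only`` / ``switch_only`` / ``both``; genes significant in
    neither are excluded.
    """
    a = de_a.set_index("gene_id")["significant"]
    b = de_b.set_index("gene_id")["significant"]
    shared = a.index.intersection(b.index)
    a, b = a.loc[shared], b.loc[shared]
    group = np.where(a & b, "both",
                     np.where(a, "direct_only", np.where(b, "switch_only", "")))
    out = pd.DataFrame({"group": group}, index=shared)
    return out[out["group"] != ""]
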