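"""Integrative bulk ↔ single-cell PCA projection.

Principal components are fitted on bulk log expression of the
pseudotime-dynamic gene set with per-gene centering and scaling. Binned
single-cell profiles are then standardised with the *bulk* per-gene mean
and SD and multiplied by the bulk rotation (loadings) matrix, placing bulk
samples and binned single-cell trajectories in one principal-component
space where direct- and trans-differentiation trajectories can be compared
directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory import BinnedProfile


@dataclass
class PCAModel:
    """Bulk PCA environment: per-gene moments plus rotation and scores."""

    genes: np.ndarray                # retained (non-degenerate) genes
    center: pd.Series                # per-gene bulk mean
    scale: pd.Series                 # per-gene bulk SD (ddof=1)
    rotation: pd.DataFrame           # genes × components (orthonormal columns)
    bulk_scores: pd.DataFrame        # samples × components
    variance_explained: np.ndarray
    dropped_genes: list


@dataclass
class ProjectedTrajectory:
    condition: str
    scores: pd.DataFrame             # bins × components
    coverage: float                  # fraction of model genes present
    imputed_genes: list


def select_dynamic_genes(de_results: list, alpha_adj: float = 0.001) -> set:
    """Union of genes with adjusted p strictly below ``alpha_adj`` in any
    pseudotime DE result."""
    genes = set()
    for de in de_results:
        padj = de["padj"].to_numpy(dtype=float)
        hit = (~np.isnan(padj)) & (padj < alpha_adj)
        genes.update(de["gene_id"].to_numpy()[hit])
    if not genes:
        raise ValueError(f"no gene passes adjusted p < {alpha_adj} in any result")
    return genes


def fit_bulk_pca(bulk_log_expr: pd.DataFrame, genes,
                 n_components: "int | None" = None) -> PCAModel:
    """SVD PCA of bulk log expression restricted to ``genes``, with per-gene
    centering and scaling.

    ``bulk_log_expr`` is a genes × samples frame of log2(normalised count + 1)
    values. Zero-variance genes are dropped and recorded. Component signs
    follow a deterministic convention: the largest-|loading| entry of each
    component is positive.
    """
    genes = [g for g in genes if g in bulk_log_expr.index]
    if bulk_log_expr.shape[1] < 3:
        raise ValueError("need at least 3 bulk samples")
    x = bulk_log_expr.loc[genes]
    center = x.mean(axis=1)
    scale = x.std(axis=1, ddof=1)
    keep = scale > 0
    dropped = list(x.index[~keep])
    x, center, scale = x[keep], center[keep], scale[keep]
    if x.shape[0] < 2:
        raise ValueError("fewer than 2 non-degenerate genes")

    z = ((x.T - center) / scale).to_numpy()  # samples × genes
    n_samples = z.shape[0]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    n_comp = min(n_components or len(s), len(s))
    rotation = vt[:n_comp].T  # genes × components
    # sign convention: largest-|loading| entry positive per component
    for c in range(n_comp):
        j = np.argmax(np.abs(rotation[:, c]))
        if rotation[j, c] < 0:
            rotation[:, c] *= -1.0
            u[:, c] *= -1.0
    scores = u[:, :n_comp] * s[:n_comp]
    var = s**2 / (n_samples - 1)
    comp_names = [f"PC{c + 1}" for c in range(n_comp)]
    return PCAModel(
        genes=x.index.to_numpy(),
        center=center,
        scale=scale,
        rotation=pd.DataFrame(rotation, index=x.index, columns=comp_names),
        bulk_scores=pd.DataFrame(scores, index=bulk_log_expr.columns,
                                 columns=comp_names),
        variance_explained=(var / var.sum())[:n_comp],
        dropped_genes=dropped,
    )


def project_binned(model: PCAModel, binned: "BinnedProfile | pd.DataFrame",
                   min_coverage: float = 0.8,
                   condition: str = "") -> ProjectedTrajectory:
    """Project a binned profile of log expression into the bulk PCA space.

    The profile is standardised with the bulk per-gene center and scale —
    not its own moments — and multiplied by the rotation matrix. Model genes
    missing from the profile are imputed at the bulk center (scaled value 0)
    provided coverage stays at or above ``min_coverage``.
    """
    frame = binned.means if isinstance(binned, BinnedProfile) else binned
    condition = condition or (binned.condition if isinstance(binned, BinnedProfile)
                              else "")
    present = [g for g in model.genes if g in frame.index]
    coverage = len(present) / len(model.genes)
    missing = [g for g in model.genes if g not in frame.index]
    if coverage < min_coverage:
        raise ValueError(
            f"profile covers {coverage:.1%} of model genes "
            f"(< {min_coverage:.0%}); missing e.g. {missing[:10]}"
        )
    z = pd.DataFrame(0.0, index=model.rotation.index, columns=frame.columns)
    sub = frame.loc[present]
    z.loc[present] = ((sub.T - model.center.loc[present])
                      / model.scale.loc[present]).T
    scores = z.T.to_numpy() @ model.rotation.to_numpy()
    return ProjectedTrajectory(
        condition,
        pd.DataFrame(scores, index=frame.columns, columns=model.rotation.columns),
        coverage, missing,
    )
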