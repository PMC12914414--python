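"""Interconversion response classification and enhancer-priming statistics.

Lineage-induced genes (padj < 0.01 and log2FC > 0 in the target 3-day vs
undifferentiated contrast) are split into commonly induced (padj < 0.05 and
log2FC > 0 in the opposing contrast) versus lineage-specific, then
subgrouped by k-means on their {undifferentiated, direct 3-day, switched}
expression profiles into genes induced more / similar / less on
interconversion. Each enhancer is linked to the gene with the nearest TSS
on the same chromosome, and Cohen's d quantifies between-group differences
of enhancer tag-density changes (chromatin accessibility by DNase-seq,
coactivator recruitment by MED1 ChIP-seq) — the readout for enhancer
priming during opposing-lineage prestimulation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .io import EnhancerTable, TssTable

RESPONSE_ORDER = ("more", "similar", "less")


def link_enhancers(enh: EnhancerTable, tss: TssTable) -> pd.DataFrame:
    """Nearest-TSS gene assignment per enhancer (midpoint distance).

    Distance is |enhancer midpoint − tss_pos| on the same chromosome; ties
    go to the smaller ``tss_pos``, then to the lexicographically smaller
    gene id. Enhancers on chromosomes without any TSS are returned unlinked
    (``gene_id = NA``).
    """
    out = []
    tss_by_chrom = dict(tuple(tss.table.groupby("chrom", sort=False)))
    for _, row in enh.table.iterrows():
        mid = 0.5 * (row["start"] + row["end"])
        sub = tss_by_chrom.get(row["chrom"])
        rec = {"enhancer_id": row["enhancer_id"], "gene_id": np.nan,
               "distance": np.nan, "tie": False}
        if sub is not None:
            d = np.abs(sub["tss_pos"].to_numpy() - mid)
            best = d.min()
            cand = sub.iloc[np.where(d == best)[0]]
            cand = cand.sort_values(["tss_pos", "gene_id"], kind="stable")
            rec.update({
                "gene_id": cand["gene_id"].iloc[0],
                "distance": mid - cand["tss_pos"].iloc[0],  # signed, mid − TSS
                "tie": len(cand) > 1,
            })
        out.append(rec)
    return pd.DataFrame(out)


def classify_induced(de_target: pd.DataFrame, de_opposing: pd.DataFrame,
                     alpha_induced: float = 0.01,
                     alpha_common: float = 0.05) -> pd.DataFrame:
    """Induced / Common / Spec labels from the two 3d-vs-MSC contrasts.

    A gene is *induced* iff padj < ``alpha_induced`` and log2fc > 0 in the
    target-lineage contrast; among induced genes, *Common* iff padj <
    ``alpha_common`` and log2fc > 0 in the opposing contrast, else *Spec*.
    """
    t = de_target.set_index("gene_id")
    o = de_opposing.set_index("gene_id")
    shared = t.index.intersection(o.index)
    if shared.empty:
        raise ValueError("contrasts share no genes")
    t, o = t.loc[shared], o.loc[shared]
    induced = (t["padj"] < alpha_induced) & (t["log2fc"] > 0)
    induced &= t["padj"].notna()
    common = (o["padj"] < alpha_common) & (o["log2fc"] > 0) & o["padj"].notna()
    commonality = np.where(common, "Common", "Spec").astype(object)
    commonality[~induced.to_numpy()] = np.nan
    return pd.DataFrame({"induced": induced, "commonality": commonality},
                        index=shared)


def kmeans_response(profiles: pd.DataFrame, k: int = 3, n_init: int = 50,
                    seed: int = 0) -> pd.Series:
    """k-means subgrouping of induced genes into more / similar / less.

    ``profiles`` is genes × 3 conditions ordered (reference/MSC, direct 3d,
    switched); rows are mean-centered before clustering — this keeps the
    labels invariant to a gene's absolute expression level without
    inflating noise for flat profiles the way per-row variance scaling
    would — and clusters are named by their mean switched-minus-direct
    contrast: highest → ``more``, lowest → ``less``, middle → ``similar``.
    """
    if profiles.shape[1] != 3:
        raise ValueError("profiles must have exactly 3 condition columns "
                         "(reference, direct, switched)")
    if len(profiles) < k:
        raise ValueError(f"need at least {k} genes, got {len(profiles)}")
    x = profiles.to_numpy(dtype=float)
    z = x - x.mean(axis=1, keepdims=True)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(z)
    contrast = z[:, 2] - z[:, 1]  # switched − direct, per gene
    cluster_contrast = np.asarray([
        contrast[km.labels_ == c].mean() for c in range(k)
    ])
    order = np.argsort(-cluster_contrast)  # highest first
    names = {}
    for rank, c in enumerate(order):
        if rank == 0:
            names[c] = "more"
        elif rank == k - 1:
            names[c] = "less"
        else:
            names[c] = "similar"
    labels = pd.Series([names[c] for c in km.labels_], index=profiles.index,
                       name="response")
    return labels


def enhancer_change(enh: EnhancerTable, mark: str, condition: str,
                    reference: str = "MSC", pseudocount: float = 1.0) -> pd.Series:
    """Per-enhancer log2 tag-density change, condition vs reference.

    ``log2((tag_cond + c) / (tag_ref + c))`` with pseudocount ``c``. When a
    precomputed fold-change column ``<mark>_log2fc_<condition>`` exists it
    is passed through unchanged.
    """
    fc_col = f"{mark}_log2fc_{condition}"
    if fc_col in enh.table.columns:
        vals = enh.table[fc_col].to_numpy(dtype=float)
    else:
        cond_col = f"{mark}_{condition}"
        ref_col = f"{mark}_{reference}"
        for col in (cond_col, ref_col):
            if col not in enh.table.columns:
                raise ValueError(f"enhancer table has no column {col!r}")
        vals = np.log2((enh.table[cond_col].to_numpy(dtype=float) + pseudocount)
                       / (enh.table[ref_col].to_numpy(dtype=float) + pseudocount))
    return pd.Series(vals, index=pd.Index(enh.table["enhancer_id"],
                                          name="enhancer_id"),
                     name=f"{mark}_{condition}_vs_{reference}")


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d with pooled SD; NA when the pooled variance is zero."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 values per group")
    s2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if s2 == 0:
        return 0.0 if a.mean() == b.mean() else np.nan
    return float((a.mean() - b.mean()) / np.sqrt(s2))


def effect_sizes(values: pd.Series, groups: pd.Series,
                 comparisons: "list[tuple[str, str]] | None" = None) -> pd.DataFrame:
    """Cohen's d for group pairs of a per-enhancer quantity.

    ``values`` and ``groups`` are aligned per enhancer; ``comparisons``
    defaults to (more, less), (more, similar), (similar, less). The sign
    follows the (first − second) convention.
    """
    values, groups = values.align(groups, join="inner")
    if comparisons is None:
        comparisons = [("more", "less"), ("more", "similar"), ("similar", "less")]
    rows = []
    for g1, g2 in comparisons:
        v1 = values[groups == g1].dropna().to_numpy()
        v2 = values[groups == g2].dropna().to_numpy()
        rows.append({
            "group_a": g1, "group_b": g2,
            "n_a": len(v1), "n_b": len(v2),
            "median_a": np.median(v1) if len(v1) else np.nan,
            "median_b": np.median(v2) if len(v2) else np.nan,
            "cohens_d": cohens_d(v1, v2) if min(len(v1), len(v2)) >= 2 else np.nan,
        })
    return pd.DataFrame(rows)


def filter_med1_bound(enh: EnhancerTable, floor: float = 0.0,
                      conditions=("MSC", "3dOb", "3dAd")) -> EnhancerTable:
    """Restrict to MED1-bound enhancers: MED1 tag density above ``floor`` in
    the undifferentiated or either 3-day condition."""
    cols = [f"MED1_{c}" for c in conditions if f"MED1_{c}" in enh.table.columns]
    if not cols:
        raise ValueError("no MED1 tag columns present")
    keep = (enh.table[cols] > floor).any(axis=1)
    return EnhancerTable(enh.table[keep].reset_index(drop=True))
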