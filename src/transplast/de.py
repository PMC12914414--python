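"""Bulk normalisation and two-group negative-binomial differential expression.

Size factors are median-of-ratios: per sample, the median over genes of the
ratio of the gene's count to its geometric mean across samples, rescaled so
the factors have geometric mean one. The two-group test is a deliberately
simple NB Wald test: per-gene dispersion is estimated by method of moments
on normalised counts, shrunk halfway toward a fitted mean-dispersion trend,
and the log2 fold change of group means (pseudocount 0.5) is divided by a
delta-method standard error from the NB variance model. Genes with all-zero
counts get ``p = NA``. Benjamini-Hochberg adjustment propagates NAs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import DE_COLUMNS, CountMatrix

_DISPERSION_FLOOR = 1e-8


def size_factors(m: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, geometric mean 1."""
    if m.n_units < 2:
        raise ValueError("size factors require at least 2 samples")
    counts = m.values.astype(float)
    all_nonzero = (counts > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; a pseudo-reference "
            "fallback would be required (not enabled)"
        )
    logc = np.log(counts[all_nonzero])
    log_geomean = logc.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logc - log_geomean, axis=0))
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=pd.Index(m.unit_ids, name="sample_id"),
                     name="size_factor")


def _fit_dispersion_trend(mean: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Parametric trend alpha(mu) = a0 + a1/mu fitted on moment estimates."""
    ok = (mean > 0) & (disp > _DISPERSION_FLOOR)
    if ok.sum() < 10:
        return np.full_like(mean, max(np.median(disp[disp > 0]), _DISPERSION_FLOOR)
                            if (disp > 0).any() else _DISPERSION_FLOOR)
    x = np.column_stack([np.ones(ok.sum()), 1.0 / mean[ok]])
    coef, *_ = np.linalg.lstsq(x, disp[ok], rcond=None)
    a0, a1 = max(coef[0], _DISPERSION_FLOOR), max(coef[1], 0.0)
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.maximum(mean, 1e-12)
    return trend


def nb_wald(m: CountMatrix, sf: pd.Series, group_a: list, group_b: list,
            pseudocount: float = 0.5, shrink_weight: float = 0.5) -> pd.DataFrame:
    """NB Wald test of ``group_a`` versus ``group_b`` (log2fc = a − b)."""
    set_a, set_b = set(group_a), set(group_b)
    if not set_a or not set_b:
        raise ValueError("both contrast groups must be nonempty")
    if set_a & set_b:
        raise ValueError(f"contrast groups overlap: {sorted(set_a & set_b)[:5]}")
    if len(set_a) < 2 or len(set_b) < 2:
        raise ValueError("need at least 2 samples per group")

    idx = pd.Index(m.unit_ids)
    pos_a = idx.get_indexer(sorted(set_a))
    pos_b = idx.get_indexer(sorted(set_b))
    if (pos_a < 0).any() or (pos_b < 0).any():
        raise ValueError("contrast names samples absent from the matrix")

    sfv = sf.loc[list(m.unit_ids)].to_numpy()
    norm = m.values / sfv  # genes × samples, normalised counts
    na, nb = len(pos_a), len(pos_b)
    xa, xb = norm[:, pos_a], norm[:, pos_b]
    mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)
    base_mean = norm.mean(axis=1)

    # method-of-moments dispersion from pooled within-group variation
    var_within = ((xa - mean_a[:, None]) ** 2).sum(axis=1)
    var_within += ((xb - mean_b[:, None]) ** 2).sum(axis=1)
    var_within /= (na + nb - 2)
    pooled_mean = (na * mean_a + nb * mean_b) / (na + nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp_mom = (var_within - pooled_mean) / pooled_mean**2
    disp_mom = np.where(np.isfinite(disp_mom), disp_mom, 0.0)
    disp_mom = np.maximum(disp_mom, _DISPERSION_FLOOR)
    trend = _fit_dispersion_trend(pooled_mean, disp_mom)
    disp = np.maximum(shrink_weight * disp_mom + (1 - shrink_weight) * trend,
                      _DISPERSION_FLOOR)

    log2fc = np.log2(mean_a + pseudocount) - np.log2(mean_b + pseudocount)

    # delta-method SE of log2 group means under var(k/s) = mu/s + alpha mu^2
    inv_sf_a = (1.0 / sfv[pos_a]).mean()
    inv_sf_b = (1.0 / sfv[pos_b]).mean()
    var_mean_a = (mean_a * inv_sf_a + disp * mean_a**2) / na
    var_mean_b = (mean_b * inv_sf_b + disp * mean_b**2) / nb
    ln2 = np.log(2.0)
    se = np.sqrt(var_mean_a / (mean_a + pseudocount) ** 2
                 + var_mean_b / (mean_b + pseudocount) ** 2) / ln2

    all_zero = m.values[:, np.concatenate([pos_a, pos_b])].sum(axis=1) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(stat))
    p = np.where(all_zero | (se == 0), np.nan, p)
    stat = np.where(np.isnan(p), np.nan, stat)

    out = pd.DataFrame({
        "gene_id": list(m.gene_ids),
        "base_mean": base_mean,
        "log2fc": log2fc,
        "se": se,
        "stat": stat,
        "p": p,
    })
    out["padj"] = adjust_bh(out["p"].to_numpy())
    return out[DE_COLUMNS]


def adjust_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up over the non-NA entries; NA propagated."""
    p = np.asarray(p, dtype=float)
    ok = ~np.isnan(p)
    if ok.any() and ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    out = np.full(p.shape, np.nan)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out
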