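"""End-to-end orchestration of the analysis stages on synthetic data.

``run_demo`` wires the stages together the way the study's analyses are
wired: simulate → QC → bulk DE → signature scoring → pseudotime
trajectories → bulk-PCA projection → enhancer classification, writing
every intermediate as TSV plus a JSON metrics file with the evaluated
pipeline properties. Every stage consumes only earlier outputs or config,
and a single global seed is expanded into per-stage seeds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import de, enhancers, projection, qc, signatures, synth, trajectory
from . import io as tio

log = logging.getLogger("transplast")

_STAGES = ("simulate", "qc", "de", "score", "trajectory", "project", "enhancers")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed: global seed + 1000 * stage index."""
    return (int(seed) + 1000 * _STAGES.index(stage)) % (2**31 - 1)


@dataclass
class AnalysisConfig:
    """Every stage threshold, with the study's defaults."""

    mito_max_pct: float = 10.0
    min_genes: int = 200
    min_frac: float = 0.10
    alpha_pt: float = 0.001        # pseudotime-DE significance (raw p)
    alpha_pt_adj: float = 0.001    # dynamic-gene selection (adjusted p)
    alpha_induced: float = 0.01
    alpha_common: float = 0.05
    bins_heatmap: int = 100
    bins_projection: int = 5
    k: int = 3                     # response k-means clusters
    kmeans_n_init: int = 50
    n_pcs: int = 20
    knn_k: int = 15
    doublet_k: int = 30
    doublet_max_score: float = 0.6  # trajectory stage excludes likely doublets
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.mito_max_pct <= 100:
            raise ValueError(f"mito_max_pct outside [0, 100]: {self.mito_max_pct}")
        for name in ("alpha_pt", "alpha_pt_adj", "alpha_induced", "alpha_common",
                     "min_frac"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} outside (0, 1]: {v}")
        for name in ("min_genes", "bins_heatmap", "bins_projection", "k",
                     "kmeans_n_init", "n_pcs", "knn_k", "doublet_k"):
            if getattr(self, name) < 1 and name != "min_genes":
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_mapping(cls, d: dict) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def bulk_log_expression(m: tio.CountMatrix) -> pd.DataFrame:
    """log2(median-of-ratios-normalised count + 1), genes × samples."""
    sf = de.size_factors(m)
    norm = m.values / sf.loc[list(m.unit_ids)].to_numpy()
    return pd.DataFrame(np.log2(norm + 1.0), index=pd.Index(m.gene_ids),
                        columns=list(m.unit_ids))


def ground_truth_signatures(gt: synth.GroundTruth):
    """Ob- and Ad-induced signature objects from the planted programs."""
    ob = tio.GeneSignature("Ob-scaled", "induced", set(gt.genes_of("ob_induced")))
    ad = tio.GeneSignature("Ad-scaled", "induced", set(gt.genes_of("ad_induced")))
    return ob, ad


def run_demo(cfg: AnalysisConfig, out_dir: "str | Path",
             n_cells_per_library: int = 600, n_genes: int = 2000) -> dict:
    """Run the whole pipeline on synthetic data; returns the metrics dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    metrics: dict = {"seed": cfg.seed}

    # ---- simulate -------------------------------------------------------
    s_sim = stage_seed(cfg.seed, "simulate")
    sc_cfg = synth.default_sc_config(seed=s_sim, n_genes=n_genes,
                                     n_cells_per_library=n_cells_per_library)
    bulk_cfg = replace(sc_cfg, seed=s_sim + 1, n_bulk_reps=3, dispersion=0.1)
    interconv_cfg = synth.default_bulk_config(seed=s_sim + 2, n_genes=n_genes,
                                              n_bulk_reps=6)
    log.info("simulate: sc %d cells/library, bulk %d reps",
             sc_cfg.n_cells_per_library, bulk_cfg.n_bulk_reps)
    sc, sc_gt = synth.generate_sc_experiment(sc_cfg)
    bulk, bulk_cond, bulk_gt = synth.generate_bulk_experiment(bulk_cfg)
    ibulk, ibulk_cond, ibulk_gt = synth.generate_bulk_experiment(interconv_cfg)
    enh, tss = synth.generate_enhancer_landscape(interconv_cfg, ibulk_gt)

    tio.write_mtx_bundle(sc, out / "sc")
    tio.write_bulk_tsv(bulk, out / "bulk_counts.tsv")
    tio.write_table(bulk_cond, out / "bulk_conditions.tsv")
    tio.write_bulk_tsv(ibulk, out / "interconv_counts.tsv")
    tio.write_table(ibulk_cond, out / "interconv_conditions.tsv")
    tio.write_bed_enhancers(enh, out / "enhancers.tsv")
    tio.write_tss(tss, out / "tss.tsv")
    ob_sig, ad_sig = ground_truth_signatures(sc_gt)
    tio.write_signature(ob_sig, out / "signature_ob.tsv")
    tio.write_signature(ad_sig, out / "signature_ad.tsv")
    truth = sc_gt.cells.copy()
    tio.write_table(truth, out / "ground_truth_cells.tsv")

    # ---- qc -------------------------------------------------------------
    qc_table = qc.compute_qc(sc, mito_prefix=sc_cfg.mito_prefix)
    kept = qc.filter_cells(qc_table, cfg.mito_max_pct, cfg.min_genes)
    scores_dbl = qc.doublet_score(sc, k=cfg.doublet_k,
                                  seed=stage_seed(cfg.seed, "qc"))
    qc_out = qc_table.join(scores_dbl)
    tio.write_table(qc_out.reset_index(), out / "qc.tsv")
    (out / "kept_barcodes.tsv").write_text("".join(f"{c}\n" for c in kept))
    metrics["qc_n_cells"] = int(sc.n_units)
    metrics["qc_n_kept"] = len(kept)

    truth_idx = truth.set_index("cell_id")
    is_dbl = truth_idx.loc[list(sc.unit_ids), "doublet"].to_numpy()
    metrics["doublet_auroc"] = float(_auroc(scores_dbl.to_numpy(), is_dbl))

    sc_kept = sc.subset_units(kept)

    # ---- bulk DE (interconversion design) -------------------------------
    sf = de.size_factors(ibulk)
    groups = ibulk_cond.groupby("library")["sample_id"].agg(list)
    de_ad = de.nb_wald(ibulk, sf, groups["Ad3"], groups["MSC"])
    de_ob = de.nb_wald(ibulk, sf, groups["Ob3"], groups["MSC"])
    tio.write_de_table(de_ad, out / "de_Ad3_vs_MSC.tsv")
    tio.write_de_table(de_ob, out / "de_Ob3_vs_MSC.tsv")

    # ---- signature scoring ----------------------------------------------
    scaled = signatures.scale_expression(sc_kept, log1p_cp10k=True, clip=10.0)
    ob_scores = signatures.score_signature(scaled, ob_sig)
    ad_scores = signatures.score_signature(scaled, ad_sig)
    libs = sc_kept.unit_meta["library"]
    dual_counts, per_cell = signatures.dual_signature_summary(
        ob_scores, ad_scores, libs, reference_label="MSC")
    tio.write_table(per_cell.reset_index(names="cell_id"), out / "scores.tsv")
    tio.write_table(dual_counts.reset_index(), out / "dual_signature_counts.tsv")

    # ---- trajectories (final osteogenic arm) -----------------------------
    s_traj = stage_seed(cfg.seed, "trajectory")
    # heterotypic doublets bridge distant states and short-circuit the kNN
    # graph, so the trajectory stage drops likely doublets by score
    keep_ids = {c for c in sc_kept.unit_ids
                if scores_dbl[c] < cfg.doublet_max_score}
    # the direct trajectory starts at the undifferentiated state, the
    # trans-differentiation trajectory at the committed adipocyte state
    direct_ids = [c for c in sc.unit_ids
                  if c in keep_ids and libs[c] in ("MSC", "Ob7")]
    switch_ids = [c for c in sc.unit_ids
                  if c in keep_ids and libs[c] in ("Ad7", "Ad7_Ob4")]
    m_direct = sc.subset_units(direct_ids)
    m_switch = sc.subset_units(switch_ids)
    pt_direct = trajectory.infer_pseudotime(m_direct, "MSC", n_pcs=cfg.n_pcs,
                                            k=cfg.knn_k, seed=s_traj)
    pt_switch = trajectory.infer_pseudotime(m_switch, "Ad7", n_pcs=cfg.n_pcs,
                                            k=cfg.knn_k, seed=s_traj)
    m_ob = sc.subset_units([c for c in direct_ids if libs[c] == "Ob7"])
    m_adob = sc.subset_units([c for c in switch_ids if libs[c] == "Ad7_Ob4"])
    de_pt_direct = trajectory.pseudotime_de(m_ob, pt_direct,
                                            min_frac=cfg.min_frac,
                                            alpha=cfg.alpha_pt)
    de_pt_switch = trajectory.pseudotime_de(m_adob, pt_switch,
                                            min_frac=cfg.min_frac,
                                            alpha=cfg.alpha_pt)
    tio.write_table(de_pt_direct, out / "pseudotime_de_direct.tsv")
    tio.write_table(de_pt_switch, out / "pseudotime_de_switch.tsv")

    merged_scaled = signatures.scale_expression(
        sc.subset_units(sorted(set(direct_ids) | set(switch_ids))),
        log1p_cp10k=True, clip=10.0)
    scaled_frame = merged_scaled.as_frame()
    bins_direct = trajectory.bin_along_pseudotime(
        scaled_frame[list(m_ob.unit_ids)], pt_direct, cfg.bins_heatmap,
        condition="Ob7")
    bins_switch = trajectory.bin_along_pseudotime(
        scaled_frame[list(m_adob.unit_ids)], pt_switch, cfg.bins_heatmap,
        condition="Ad7_Ob4")
    grp = trajectory.group_by_significance(de_pt_direct, de_pt_switch)
    sig_genes = list(grp.index)
    corr = trajectory.cross_condition_correlation(bins_direct, bins_switch,
                                                  genes=sig_genes)
    tio.write_table(corr.reset_index(), out / "trajectory_correlation.tsv")
    tio.write_table(grp.reset_index(names="gene_id"),
                    out / "trajectory_groups.tsv")
    ob_genes = [g for g in sc_gt.genes_of("ob_induced") if g in corr.index]
    metrics["median_r_ob_genes"] = float(np.nanmedian(corr.loc[ob_genes])) \
        if ob_genes else float("nan")
    by_group = corr.to_frame().join(grp)
    med = by_group.groupby("group")["pearson_r"].median()
    metrics["median_r_by_group"] = {k: float(v) for k, v in med.items()}

    # ---- projection ------------------------------------------------------
    dyn = projection.select_dynamic_genes([de_pt_direct, de_pt_switch],
                                          alpha_adj=cfg.alpha_pt_adj)
    blx = bulk_log_expression(bulk)
    pca = projection.fit_bulk_pca(blx, sorted(dyn))
    lognorm = pd.DataFrame(trajectory._log1p_cp10k(sc.values),
                           index=pd.Index(sc.gene_ids), columns=list(sc.unit_ids))
    bins5_direct = trajectory.bin_along_pseudotime(
        lognorm[[c for c in direct_ids if libs[c] == "Ob7"]], pt_direct,
        cfg.bins_projection, condition="Ob7")
    bins5_switch = trajectory.bin_along_pseudotime(
        lognorm[[c for c in switch_ids if libs[c] == "Ad7_Ob4"]], pt_switch,
        cfg.bins_projection, condition="Ad7_Ob4")
    proj_direct = projection.project_binned(pca, bins5_direct)
    proj_switch = projection.project_binned(pca, bins5_switch)
    proj_tab = pd.concat([
        pca.bulk_scores.assign(kind="bulk", condition=list(pca.bulk_scores.index)),
        proj_direct.scores.assign(kind="sc", condition="Ob7"),
        proj_switch.scores.assign(kind="sc", condition="Ad7_Ob4"),
    ])
    tio.write_table(proj_tab.reset_index(names="point"), out / "projection.tsv")

    self_proj = projection.project_binned(pca, blx)
    rel = np.abs(self_proj.scores.to_numpy() - pca.bulk_scores.to_numpy())
    denom = np.abs(pca.bulk_scores.to_numpy()).max()
    metrics["self_projection_max_rel_err"] = float(rel.max() / denom)
    pc1_range = float(pca.bulk_scores["PC1"].max() - pca.bulk_scores["PC1"].min())
    term_gap = abs(float(proj_direct.scores["PC1"].iloc[-1])
                   - float(proj_switch.scores["PC1"].iloc[-1]))
    metrics["terminal_pc1_gap_frac"] = term_gap / pc1_range

    # ---- enhancers (Fig 7-style, adipogenic arm) -------------------------
    cls = enhancers.classify_induced(de_ad, de_ob, cfg.alpha_induced,
                                     cfg.alpha_common)
    induced = cls.index[cls["induced"]]
    iblx = bulk_log_expression(ibulk)
    cond_means = iblx.T.groupby(ibulk_cond.set_index("sample_id")["library"]).mean().T
    profiles = cond_means.loc[induced, ["MSC", "Ad3", "Ob3_Ad4"]]
    resp = enhancers.kmeans_response(profiles, k=cfg.k, n_init=cfg.kmeans_n_init,
                                     seed=stage_seed(cfg.seed, "enhancers"))
    links = enhancers.link_enhancers(enhancers.filter_med1_bound(enh), tss)
    links = links.merge(resp.rename("response"), left_on="gene_id",
                        right_index=True, how="inner")
    change = enhancers.enhancer_change(enh, "DNase", "3dOb")
    med1_change = enhancers.enhancer_change(enh, "MED1", "3dOb")
    eff = []
    for mark, ch in (("DNase", change), ("MED1", med1_change)):
        e = enhancers.effect_sizes(ch.loc[links["enhancer_id"]].set_axis(
            links["enhancer_id"]), links.set_index("enhancer_id")["response"])
        e.insert(0, "mark", mark)
        e.insert(1, "quantity", "prestim_change")
        eff.append(e)
    for mark in ("DNase", "MED1"):
        basal = pd.Series(enh.table[f"{mark}_MSC"].to_numpy(),
                          index=enh.table["enhancer_id"])
        e = enhancers.effect_sizes(basal.loc[links["enhancer_id"]],
                                   links.set_index("enhancer_id")["response"])
        e.insert(0, "mark", mark)
        e.insert(1, "quantity", "basal_level")
        eff.append(e)
    eff_table = pd.concat(eff, ignore_index=True)
    resp_out = cls.copy()
    resp_out["response"] = resp.reindex(cls.index)
    tio.write_table(resp_out.reset_index(names="gene_id"),
                    out / "response_groups.tsv")
    tio.write_table(eff_table, out / "effect_sizes.tsv")

    truth_resp = ibulk_gt.response_labels.reindex(resp.index)
    ok = truth_resp.notna()
    metrics["kmeans_response_recovery"] = float(
        (resp[ok] == truth_resp[ok]).mean()) if ok.any() else float("nan")
    d_row = eff_table[(eff_table["mark"] == "DNase")
                      & (eff_table["quantity"] == "prestim_change")
                      & (eff_table["group_a"] == "more")
                      & (eff_table["group_b"] == "less")]
    metrics["priming_cohens_d_dnase"] = float(d_row["cohens_d"].iloc[0])

    with open(out / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
    from . import __version__

    run_record = {
        "config": asdict(cfg),
        "stage_seeds": {s: stage_seed(cfg.seed, s) for s in _STAGES},
        "version": __version__,
    }
    with open(out / "run_config.json", "w") as fh:
        json.dump(run_record, fh, indent=2, sort_keys=True)
    return metrics


def _auroc(score: np.ndarray, label: np.ndarray) -> float:
    """Rank-based AUROC (Mann-Whitney)."""
    from scipy.stats import rankdata

    label = np.asarray(label, dtype=bool)
    n1, n0 = label.sum(), (~label).sum()
    if n1 == 0 or n0 == 0:
        return float("nan")
    r = rankdata(score)
    return float((r[label].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))
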