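"""Synthetic bulk / single-cell / enhancer data with known ground truth.

The generator emulates the in-vitro trans-differentiation designs this
package analyses: bone-marrow stromal cells exposed to osteogenic (``ob``)
or adipogenic (``ad``) inducer cocktails, with single or repeated switches
between them. Gene programs (osteoblast-induced, adipocyte-induced,
adipocyte-repressed, commonly induced, stem-cell) respond to cumulative
inducer exposure through a logistic activation curve; on a media switch the
old program decays and the new one rises with the same kinetics, so direct-
and trans-differentiated populations converge to the same terminal state.

Counts are negative-binomial (``var = mu + alpha * mu**2``). Single-cell
libraries add a refractory subpopulation that ignores the switch, planted
doublets, per-cell mitochondrial-fraction and library-size variation. The
enhancer landscape places 1-3 enhancers next to each gene's TSS on one
pseudo-chromosome and can plant a "priming" tag-density boost, during
opposing-lineage prestimulation, at enhancers of genes that respond more
strongly to interconversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import CountMatrix, EnhancerTable, TssTable

PROGRAMS = ("ob_induced", "ad_induced", "ad_repressed", "common_induced", "stem", "null")

# inducers that drive each program, and the sign of the response
_PROGRAM_DRIVERS = {
    "ob_induced": ({"ob"}, +1.0),
    "ad_induced": ({"ad"}, +1.0),
    "ad_repressed": ({"ad"}, -1.0),
    "common_induced": ({"ob", "ad"}, +1.0),
    "stem": ({"ob", "ad"}, -1.0),
    "null": (set(), 0.0),
}

RESPONSE_LABELS = ("more", "similar", "less")
_RESPONSE_SIGN = {"more": +1.0, "similar": 0.0, "less": -1.0}

Schedule = "list[tuple[str, float]]"  # [(inducer in {ob, ad, none}, days), ...]


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """All knobs of the simulated study.

    ``design`` maps library ids to inducer schedules; a schedule is a list of
    ``(inducer, duration_days)`` segments. The default program sizes keep the
    roughly 1 : 1.2 : 2.6 proportions of the osteoblast-induced /
    adipocyte-induced / adipocyte-repressed signatures at a 2000-gene scale.
    """

    n_genes: int = 2000
    program_sizes: dict = field(default_factory=lambda: {
        "ob_induced": 120, "ad_induced": 147, "ad_repressed": 315,
        "common_induced": 80, "stem": 80,
    })
    n_mito_genes: int = 10
    mito_prefix: str = "MT-"
    n_cells_per_library: int = 1000
    n_bulk_reps: int = 3
    design: list = field(default_factory=lambda: [
        ("MSC", [("none", 7.0)]),
        ("Ob7", [("ob", 7.0)]),
        ("Ad7", [("ad", 7.0)]),
        ("Ad7_Ob4", [("ad", 7.0), ("ob", 4.0)]),
        ("Ob7_Ad4", [("ob", 7.0), ("ad", 4.0)]),
    ])
    logfc_scale: float = 2.0          # log2 units at full program activation
    dispersion: float = 0.1           # NB alpha, var = mu + alpha mu^2
    refractory_fraction: float = 0.1  # switch libraries only
    doublet_fraction: float = 0.05
    mito_mean: float = 0.05
    mito_sd: float = 0.02
    bulk_depth_lognormal: tuple = (math.log(4e5), 0.15)
    cell_depth_lognormal: tuple = (math.log(5000.0), 0.35)
    fixed_depths: "list | None" = None  # bulk: explicit per-sample depths
    activation_midpoint: float = 1.5  # days of net exposure to half-activate
    activation_steepness: float = 0.6
    decay_rate: float = 2.5           # program decay speed relative to rise
    response_logfc: float = 1.0       # interconversion more/less modifier, log2
    delta_prime: float = 10.0         # additive enhancer-priming tag boost
    tag_lognormal: tuple = (math.log(10.0), 0.5)
    weight_sigma: float = 1.0         # lognormal spread of baseline expression
    gene_spacing: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.program_sizes.values()) + self.n_mito_genes
        if total > self.n_genes:
            raise ConfigError(
                f"program sizes + mito genes ({total}) exceed n_genes ({self.n_genes})"
            )
        for name in ("refractory_fraction", "doublet_fraction", "mito_mean", "mito_sd"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} = {v} outside [0, 1]")
        if self.dispersion < 0:
            raise ConfigError(f"dispersion must be >= 0, got {self.dispersion}")
        unknown = set(self.program_sizes) - set(PROGRAMS)
        if unknown:
            raise ConfigError(f"unknown programs {sorted(unknown)}")


def default_bulk_config(**overrides) -> SimConfig:
    """Bulk interconversion design: 3-day commitment ± 4-day opposing switch."""
    cfg = SimConfig(design=[
        ("MSC", [("none", 3.0)]),
        ("Ob3", [("ob", 3.0)]),
        ("Ad3", [("ad", 3.0)]),
        ("Ob3_Ad4", [("ob", 3.0), ("ad", 4.0)]),
        ("Ad3_Ob4", [("ad", 3.0), ("ob", 4.0)]),
    ])
    return replace(cfg, **overrides)


def default_sc_config(**overrides) -> SimConfig:
    """Single-cell design: direct 7-day versus 7 + 4-day switched libraries.

    UMI-level counts carry little extra-Poisson noise, hence the smaller
    dispersion; the interconversion response modifier is zero so that direct
    and switched libraries share their terminal program state exactly.
    """
    cfg = SimConfig(dispersion=0.05, response_logfc=0.0)
    return replace(cfg, **overrides)


@dataclass
class GroundTruth:
    """Everything the generators know that the pipeline must re-discover."""

    gene_programs: pd.Series          # gene_id -> program label
    response_labels: pd.Series        # gene_id -> more/similar/less (NaN if n/a)
    config: SimConfig
    samples: "pd.DataFrame | None" = None  # bulk: sample_id, library, schedule
    cells: "pd.DataFrame | None" = None    # sc: cell_id, library, t, refractory, doublet
    enhancer_priming: "pd.Series | None" = None  # enhancer_id -> primed condition or NaN

    def genes_of(self, program: str) -> np.ndarray:
        return self.gene_programs.index[self.gene_programs == program].to_numpy()


# ---------------------------------------------------------------------------
# activation kinetics


def _exposure(schedule, drivers: set, time: float, decay_rate: float) -> float:
    """Net driving exposure at ``time``: +dt under a driving inducer,
    -decay_rate*dt otherwise, floored at zero. Decay faster than rise
    reproduces the rapid obliteration of the old program on a media switch."""
    e, elapsed = 0.0, 0.0
    for inducer, dur in schedule:
        seg = min(dur, max(0.0, time - elapsed))
        e = e + seg if inducer in drivers else max(0.0, e - decay_rate * seg)
        elapsed += dur
        if elapsed >= time:
            break
    return e

def _logistic_activation(e: float, midpoint: float, steepness: float) -> float:
    s0 = 1.0 / (1.0 + math.exp(midpoint / steepness))
    s = 1.0 / (1.0 + math.exp(-(e - midpoint) / steepness))
    return (s - s0) / (1.0 - s0)


def program_activation(program: str, schedule, time: float, cfg: SimConfig) -> float:
    """Activation a in [0, 1] of a gene program at ``time`` days along ``schedule``."""
    drivers, _sign = _PROGRAM_DRIVERS[program]
    if not drivers:
        return 0.0
    e = _exposure(schedule, drivers, time, cfg.decay_rate)
    return _logistic_activation(e, cfg.activation_midpoint, cfg.activation_steepness)


def _schedule_duration(schedule) -> float:
    return sum(d for _i, d in schedule)


def _is_switch(schedule) -> bool:
    inducers = [i for i, _d in schedule if i != "none"]
    return len(set(inducers)) >= 2


def _final_inducer(schedule):
    inducers = [i for i, _d in schedule if i != "none"]
    return inducers[-1] if inducers else "none"


def _frozen_schedule(schedule):
    """Schedule a refractory cell experiences: first inducer held throughout."""
    first = next((i for i, _d in schedule if i != "none"), "none")
    return [(first, _schedule_duration(schedule))]


def schedule_string(schedule) -> str:
    return "|".join(f"{i}:{d:g}" for i, d in schedule)


# ---------------------------------------------------------------------------
# expression means


def _assign_genes(cfg: SimConfig, rng: np.random.Generator):
    """Gene ids, program labels, baseline weights, response labels, signs."""
    gene_ids, programs = [], []
    for i in range(cfg.n_mito_genes):
        gene_ids.append(f"{cfg.mito_prefix}G{i + 1}")
        programs.append("null")
    counter = 0
    for prog in PROGRAMS[:-1]:
        for _ in range(cfg.program_sizes.get(prog, 0)):
            counter += 1
            gene_ids.append(f"G{counter:04d}")
            programs.append(prog)
    while len(gene_ids) < cfg.n_genes:
        counter += 1
        gene_ids.append(f"G{counter:04d}")
        programs.append("null")
    gene_ids = np.asarray(gene_ids, dtype=object)
    programs = pd.Series(programs, index=gene_ids, name="program")

    weights = rng.lognormal(0.0, cfg.weight_sigma, size=cfg.n_genes)
    is_mito = np.asarray([g.startswith(cfg.mito_prefix) for g in gene_ids])
    if is_mito.any():
        weights[is_mito] *= cfg.mito_mean / weights[is_mito].sum()
        weights[~is_mito] *= (1.0 - cfg.mito_mean) / weights[~is_mito].sum()
    else:
        weights /= weights.sum()

    # every lineage-induced gene gets an interconversion response label
    response = pd.Series(np.nan, index=gene_ids, dtype=object, name="response")
    for prog in ("ob_induced", "ad_induced", "common_induced"):
        idx = programs.index[programs == prog].to_numpy()
        labels = np.asarray(RESPONSE_LABELS)[np.arange(len(idx)) % 3]
        response.loc[idx] = labels[rng.permutation(len(idx))]
    return gene_ids, programs, weights, response


class _EffectModel:
    """Precomputed per-gene arrays so per-unit log2 effects are vector ops."""

    def __init__(self, programs: pd.Series, response: pd.Series, cfg: SimConfig):
        self.cfg = cfg
        self.masks = {p: (programs == p).to_numpy() for p in PROGRAMS[:-1]}
        self.signs = {p: _PROGRAM_DRIVERS[p][1] for p in PROGRAMS[:-1]}
        resp = response.to_numpy(dtype=object)
        self.resp_sign = np.asarray([_RESPONSE_SIGN.get(r, 0.0) for r in resp])

    def log2_effects(self, schedule, time: float, refractory: bool = False) -> np.ndarray:
        """Per-gene log2 mean shift at ``time`` days along ``schedule``."""
        cfg = self.cfg
        sched = _frozen_schedule(schedule) if refractory else schedule
        lfc = np.zeros(len(self.resp_sign))
        acts = {p: program_activation(p, sched, time, cfg) for p in PROGRAMS[:-1]}
        for prog, mask in self.masks.items():
            lfc[mask] = cfg.logfc_scale * self.signs[prog] * acts[prog]
        if cfg.response_logfc != 0.0 and not refractory and _is_switch(sched):
            final = _final_inducer(sched)
            target = {"ob": "ob_induced", "ad": "ad_induced"}.get(final)
            if target is not None:
                for prog in (target, "common_induced"):
                    mask = self.masks[prog]
                    lfc[mask] += cfg.response_logfc * self.resp_sign[mask] * acts[prog]
        return lfc


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    if alpha < 1e-12:
        return rng.poisson(mu)
    n = 1.0 / alpha
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


# ---------------------------------------------------------------------------
# generators


def generate_bulk_experiment(cfg: SimConfig):
    """Simulate the bulk RNA-seq design.

    Returns ``(CountMatrix, condition_table, GroundTruth)``. Expected counts
    are ``depth_j * q_g * 2**lfc_gj`` with NB noise; replicates share a
    schedule and differ only in depth and sampling noise.
    """
    rng = np.random.default_rng(cfg.seed)
    gene_ids, programs, weights, response = _assign_genes(cfg, rng)

    sample_ids, libraries, schedules = [], [], []
    for lib, sched in cfg.design:
        for rep in range(1, cfg.n_bulk_reps + 1):
            sample_ids.append(f"{lib}_r{rep}")
            libraries.append(lib)
            schedules.append(sched)
    n_samples = len(sample_ids)

    if cfg.fixed_depths is not None:
        if len(cfg.fixed_depths) != n_samples:
            raise ConfigError(
                f"fixed_depths has {len(cfg.fixed_depths)} entries for {n_samples} samples"
            )
        depths = np.asarray(cfg.fixed_depths, dtype=float)
    else:
        mu, sd = cfg.bulk_depth_lognormal
        depths = rng.lognormal(mu, sd, size=n_samples)

    effects = _EffectModel(programs, response, cfg)
    counts = np.empty((cfg.n_genes, n_samples), dtype=np.int64)
    for j, sched in enumerate(schedules):
        t_end = _schedule_duration(sched)
        lfc = effects.log2_effects(sched, t_end)
        w = weights * np.exp2(lfc)
        mu_j = depths[j] * w / w.sum()  # depth is the expected library size
        counts[:, j] = _nb_draw(rng, mu_j, cfg.dispersion)

    condition_table = pd.DataFrame({
        "sample_id": sample_ids,
        "library": libraries,
        "schedule": [schedule_string(s) for s in schedules],
    })
    m = CountMatrix(counts, gene_ids, np.asarray(sample_ids, dtype=object),
                    condition_table.set_index("sample_id"))
    samples = condition_table.copy()
    samples["depth"] = depths
    gt = GroundTruth(programs, response, cfg, samples=samples)
    return m, condition_table, gt


def generate_sc_experiment(cfg: SimConfig):
    """Simulate the single-cell design.

    Each cell sits at ``t ~ Uniform[0, 1]`` along the final inducer segment
    of its library's schedule, with all earlier segments completed — the
    libraries are harvested after the full protocol, so asynchrony spreads
    cells along the current (last) differentiation phase, not back to the
    undifferentiated state. Refractory cells in switch libraries keep the
    pre-switch program active; doublets are appended as depth-thinned sums
    of two random cells and flagged in the ground truth.
    """
    if cfg.n_cells_per_library <= 0:
        raise ConfigError("n_cells_per_library must be positive")
    rng = np.random.default_rng(cfg.seed)
    gene_ids, programs, weights, response = _assign_genes(cfg, rng)
    is_mito = np.asarray([g.startswith(cfg.mito_prefix) for g in gene_ids])
    effects = _EffectModel(programs, response, cfg)

    cell_ids, cell_lib, cell_t, cell_refr = [], [], [], []
    rows = []
    mu_depth, sd_depth = cfg.cell_depth_lognormal
    for lib, sched in cfg.design:
        t_total = _schedule_duration(sched)
        t_base = t_total - sched[-1][1]  # completed earlier segments
        switch = _is_switch(sched)
        t = rng.uniform(0.0, 1.0, size=cfg.n_cells_per_library)
        refr = (rng.uniform(size=cfg.n_cells_per_library) < cfg.refractory_fraction) \
            if switch else np.zeros(cfg.n_cells_per_library, dtype=bool)
        depths = rng.lognormal(mu_depth, sd_depth, size=cfg.n_cells_per_library)
        mito_f = np.clip(rng.normal(cfg.mito_mean, cfg.mito_sd,
                                    size=cfg.n_cells_per_library), 0.002, 0.6)
        for i in range(cfg.n_cells_per_library):
            lfc = effects.log2_effects(sched, t_base + t[i] * sched[-1][1],
                                       refractory=bool(refr[i]))
            w = weights * np.exp2(lfc)
            if is_mito.any() and cfg.mito_mean > 0:
                w[is_mito] *= mito_f[i] / cfg.mito_mean
            mu_c = depths[i] * w / w.sum()
            rows.append(_nb_draw(rng, mu_c, cfg.dispersion))
            cell_ids.append(f"{lib}_c{i + 1:04d}")
            cell_lib.append(lib)
            cell_t.append(t[i])
            cell_refr.append(bool(refr[i]))

    counts = np.stack(rows, axis=1)
    n_singlets = counts.shape[1]
    n_doublets = int(round(cfg.doublet_fraction * n_singlets))
    doublet_flags = [False] * n_singlets
    if n_doublets:
        pairs = rng.integers(0, n_singlets, size=(n_doublets, 2))
        dbl = np.empty((cfg.n_genes, n_doublets), dtype=np.int64)
        for d, (a, b) in enumerate(pairs):
            summed = counts[:, a] + counts[:, b]
            total = summed.sum()
            # renormalise to 1.8x the mean single-cell depth of the pair
            target = 0.9 * total
            dbl[:, d] = rng.binomial(summed, min(1.0, target / max(total, 1)))
            cell_ids.append(f"DBL_c{d + 1:04d}")
            cell_lib.append(cell_lib[a])
            cell_t.append(0.5 * (cell_t[a] + cell_t[b]))
            cell_refr.append(False)
            doublet_flags.append(True)
        counts = np.concatenate([counts, dbl], axis=1)

    cells = pd.DataFrame({
        "cell_id": cell_ids,
        "library": cell_lib,
        "t": cell_t,
        "refractory": cell_refr,
        "doublet": doublet_flags,
    })
    meta = cells.set_index("cell_id")[["library"]]
    m = CountMatrix(counts, gene_ids, np.asarray(cell_ids, dtype=object), meta)
    gt = GroundTruth(programs, response, cfg, cells=cells)
    return m, gt


# priming targets: a gene's enhancers gain tags during the OPPOSING lineage's
# 3-day prestimulation
_OPPOSING_CONDITION = {"ad_induced": "3dOb", "ob_induced": "3dAd"}

TAG_CONDITIONS = ("MSC", "3dOb", "3dAd")
TAG_MARKS = ("DNase", "MED1")


def generate_enhancer_landscape(cfg: SimConfig, gt: GroundTruth):
    """Place 1-3 enhancers near each gene's TSS on one pseudo-chromosome and
    draw lognormal DNase/MED1 tag densities for MSC, 3dOb and 3dAd.

    Enhancers of lineage-induced genes gain tags in their own lineage's 3-day
    condition (enhancer activation tracks transcription); enhancers of genes
    planted as "more induced on interconversion" additionally receive
    ``delta_prime`` during opposing-lineage prestimulation.
    """
    rng = np.random.default_rng(cfg.seed + 104729)  # decoupled stream
    genes = gt.gene_programs.index.to_numpy()
    tss_pos = 5000 + cfg.gene_spacing * np.arange(len(genes))
    strands = np.where(rng.uniform(size=len(genes)) < 0.5, "+", "-")
    tss = TssTable(pd.DataFrame({
        "gene_id": genes, "chrom": "chrS", "tss_pos": tss_pos, "strand": strands,
    }))

    half = cfg.gene_spacing // 2 - 1000  # keep enhancers nearest their own TSS
    recs, priming = [], {}
    mu_tag, sd_tag = cfg.tag_lognormal
    eid = 0
    for i, g in enumerate(genes):
        prog = gt.gene_programs[g]
        resp = gt.response_labels[g]
        n_enh = int(rng.integers(1, 4))
        for _ in range(n_enh):
            eid += 1
            offset = float(rng.uniform(500, half)) * (1 if rng.uniform() < 0.5 else -1)
            width = int(rng.integers(200, 1000))
            mid = tss_pos[i] + offset
            start = max(0, int(round(mid - width / 2)))
            end = start + width
            tags = {}
            for mark in TAG_MARKS:
                for cond in TAG_CONDITIONS:
                    v = rng.lognormal(mu_tag, sd_tag)
                    # lineage activation: own-lineage 3d condition gains tags
                    if (prog == "ob_induced" and cond == "3dOb") or \
                       (prog in ("ad_induced", "common_induced") and cond == "3dAd") or \
                       (prog == "common_induced" and cond == "3dOb"):
                        v *= 2.0
                    tags[f"{mark}_{cond}"] = v
            primed_cond = _OPPOSING_CONDITION.get(prog) if resp == "more" else None
            if primed_cond is not None and cfg.delta_prime != 0.0:
                for mark in TAG_MARKS:
                    tags[f"{mark}_{primed_cond}"] += cfg.delta_prime
            priming[f"E{eid:05d}"] = primed_cond
            recs.append({"chrom": "chrS", "start": start, "end": end,
                         "enhancer_id": f"E{eid:05d}", **tags})

    enh = EnhancerTable(pd.DataFrame(recs))
    gt.enhancer_priming = pd.Series(priming, name="primed_condition")
    return enh, tss
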