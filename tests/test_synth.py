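"""Ground-truth and distributional guarantees of the data generator."""

import io as stdio

import numpy as np
import pytest
from scipy.stats import ks_2samp

from transplast import synth
from transplast.synth import SimConfig, program_activation


def small_cfg(**kw):
    base = dict(n_genes=400, n_mito_genes=4,
                program_sizes={"ob_induced": 40, "ad_induced": 40,
                               "ad_repressed": 40, "common_induced": 20,
                               "stem": 20},
                n_cells_per_library=120, n_bulk_reps=3, seed=0)
    base.update(kw)
    return SimConfig(**base)


class TestConfig:
    def test_oversized_programs_rejected(self):
        with pytest.raises(synth.ConfigError, match="exceed"):
            SimConfig(n_genes=100, program_sizes={"ob_induced": 200})

    def test_bad_proportions_rejected(self):
        with pytest.raises(synth.ConfigError):
            SimConfig(refractory_fraction=1.5)

    def test_zero_cells_rejected(self):
        with pytest.raises(synth.ConfigError, match="positive"):
            synth.generate_sc_experiment(small_cfg(n_cells_per_library=0))


class TestActivation:
    def test_rises_with_exposure_and_zero_at_start(self):
        cfg = small_cfg()
        sched = [("ob", 7.0)]
        acts = [program_activation("ob_induced", sched, t, cfg)
                for t in (0, 1, 2, 4, 7)]
        assert acts[0] == 0.0
        assert all(b > a for a, b in zip(acts, acts[1:]))
        assert acts[-1] > 0.95

    def test_switch_decays_old_program(self):
        cfg = small_cfg()
        sched = [("ad", 7.0), ("ob", 4.0)]
        assert program_activation("ad_induced", sched, 7.0, cfg) > 0.95
        assert program_activation("ad_induced", sched, 11.0, cfg) < 0.05
        assert program_activation("ob_induced", sched, 11.0, cfg) > 0.95

    def test_terminal_convergence_direct_vs_switch(self):
        """Direct 7d and 7+4d switched schedules end at nearly the same
        osteogenic activation (generative terminal states converge)."""
        cfg = small_cfg()
        a_direct = program_activation("ob_induced", [("ob", 7.0)], 7.0, cfg)
        a_switch = program_activation("ob_induced",
                                      [("ad", 7.0), ("ob", 4.0)], 11.0, cfg)
        assert 2 ** (2 * abs(a_direct - a_switch)) - 1 < 0.05


class TestBulk:
    def test_deterministic_under_seed(self):
        m1, c1, _ = synth.generate_bulk_experiment(small_cfg(seed=1))
        m2, c2, _ = synth.generate_bulk_experiment(small_cfg(seed=1))
        assert np.array_equal(m1.values, m2.values)
        assert c1.equals(c2)

    def test_null_effect_gives_identical_means(self):
        """With logfc_scale=0 and fixed depths every sample shares the same
        expected counts; observed group means agree within Poisson noise."""
        cfg = small_cfg(n_genes=2000, program_sizes={}, n_mito_genes=0,
                        logfc_scale=0.0, dispersion=0.0, n_bulk_reps=6,
                        design=[("A", [("ob", 3.0)]), ("B", [("none", 3.0)])],
                        fixed_depths=[2e5] * 12)
        m, _, _ = synth.generate_bulk_experiment(cfg)
        mean_a = m.values[:, :6].mean(1)
        mean_b = m.values[:, 6:].mean(1)
        se = np.sqrt((mean_a + mean_b) / 6)
        z = (mean_a - mean_b) / np.maximum(se, 1e-9)
        assert np.abs(z).mean() < 1.0  # standard-normal scale

    def test_mom_log2fc_recovery(self):
        """Planted 2-log2 induction is recovered by method-of-moments on
        size-factor-normalised counts over 500 planted genes."""
        from transplast import de

        cfg = SimConfig(seed=62, n_genes=10000, logfc_scale=2.0, n_bulk_reps=6,
                        dispersion=0.01, n_mito_genes=0,
                        program_sizes={"ob_induced": 500},
                        design=[("OB", [("ob", 30.0)]),
                                ("CTRL", [("none", 1.0)])])
        m, _, gt = synth.generate_bulk_experiment(cfg)
        norm = m.values / de.size_factors(m).to_numpy()
        planted = np.isin(m.gene_ids, gt.genes_of("ob_induced"))
        mom = np.log2(norm[:, :6].mean(1) + 0.5) - np.log2(norm[:, 6:].mean(1) + 0.5)
        assert mom[planted].mean() == pytest.approx(2.0, abs=0.1)

    def test_logfc_monotonicity(self):
        """Stronger logfc_scale strictly increases the planted |log2FC|."""
        fcs = []
        for scale in (0.5, 1.0, 2.0):
            cfg = small_cfg(seed=3, logfc_scale=scale, dispersion=0.0,
                            n_bulk_reps=2,
                            design=[("OB", [("ob", 30.0)]),
                                    ("CTRL", [("none", 1.0)])],
                            fixed_depths=[4e5] * 4)
            m, _, gt = synth.generate_bulk_experiment(cfg)
            planted = np.isin(m.gene_ids, gt.genes_of("ob_induced"))
            lfc = np.log2(m.values[planted, :2].mean(1) + 0.5) \
                - np.log2(m.values[planted, 2:].mean(1) + 0.5)
            fcs.append(np.abs(lfc).mean())
        assert fcs[0] < fcs[1] < fcs[2]


class TestNbSampler:
    @pytest.mark.parametrize("mu,alpha", [(2.0, 0.05), (20.0, 0.1), (200.0, 0.1)])
    def test_moment_recovery(self, mu, alpha):
        """Sample mean/variance match NB(mu, alpha) within 3 SE at n=10000."""
        rng = np.random.default_rng(99)
        x = synth._nb_draw(rng, np.full(10_000, mu), alpha)
        var = mu + alpha * mu**2
        se_mean = np.sqrt(var / 10_000)
        assert abs(x.mean() - mu) < 3 * se_mean
        # SE of the sample variance from the 4th central moment
        m4 = ((x - x.mean()) ** 4).mean()
        se_var = np.sqrt((m4 - var**2) / 10_000)
        assert abs(x.var(ddof=1) - var) < 3 * se_var


class TestSingleCell:
    def test_flags_all_false_without_nuisances(self):
        sc, gt = synth.generate_sc_experiment(
            small_cfg(refractory_fraction=0.0, doublet_fraction=0.0))
        assert not gt.cells["refractory"].any()
        assert not gt.cells["doublet"].any()

    def test_doublet_count_exact(self):
        cfg = small_cfg(n_cells_per_library=200, doublet_fraction=0.1,
                        design=[("A", [("ob", 7.0)]),
                                ("B", [("ad", 7.0)]),
                                ("C", [("none", 7.0)]),
                                ("D", [("ad", 7.0), ("ob", 4.0)]),
                                ("E", [("ob", 7.0), ("ad", 4.0)])])
        sc, gt = synth.generate_sc_experiment(cfg)
        assert gt.cells["doublet"].sum() == 100  # 10% of 1000 cells appended
        assert sc.n_units == 1100

    def test_refractory_keep_preswitch_program(self):
        cfg = small_cfg(seed=4, refractory_fraction=0.3, doublet_fraction=0.0,
                        logfc_scale=3.0,
                        design=[("SW", [("ad", 7.0), ("ob", 7.0)])])
        sc, gt = synth.generate_sc_experiment(cfg)
        truth = gt.cells.set_index("cell_id")
        ad_genes = gt.genes_of("ad_induced")
        idx = np.isin(sc.gene_ids, ad_genes)
        frac_ad = sc.values[idx].sum(0) / sc.values.sum(0)
        late = truth["t"].to_numpy() > 0.6
        refr = truth["refractory"].to_numpy()
        assert frac_ad[late & refr].mean() > 2 * frac_ad[late & ~refr].mean()

    def test_seed_reproducibility(self):
        a, _ = synth.generate_sc_experiment(small_cfg(seed=7))
        b, _ = synth.generate_sc_experiment(small_cfg(seed=7))
        assert np.array_equal(a.values, b.values)
        assert list(a.unit_ids) == list(b.unit_ids)


class TestEnhancerLandscape:
    def test_nearest_tss_is_own_gene(self):
        cfg = small_cfg()
        _, gt = synth.generate_sc_experiment(cfg)
        enh, tss = synth.generate_enhancer_landscape(cfg, gt)
        from transplast.enhancers import link_enhancers

        links = link_enhancers(enh, tss).set_index("enhancer_id")
        pos = tss.table.set_index("gene_id")["tss_pos"]
        for _, row in enh.table.iterrows():
            mid = 0.5 * (row["start"] + row["end"])
            linked = links.loc[row["enhancer_id"], "gene_id"]
            assert abs(pos[linked] - mid) <= cfg.gene_spacing / 2

    def test_null_priming_indistinguishable(self):
        """With delta_prime = 0 the prestimulation tag-change distributions
        of 'more' vs 'less' genes' enhancers coincide (KS p > 0.01)."""
        cfg = synth.default_bulk_config(seed=77, delta_prime=0.0, n_genes=4000,
                                        program_sizes={"ob_induced": 300,
                                                       "ad_induced": 450,
                                                       "ad_repressed": 600,
                                                       "common_induced": 200,
                                                       "stem": 200})
        _, _, gt = synth.generate_bulk_experiment(cfg)
        enh, tss = synth.generate_enhancer_landscape(cfg, gt)
        from transplast.enhancers import enhancer_change, link_enhancers

        links = link_enhancers(enh, tss).merge(
            gt.response_labels.rename("response"), left_on="gene_id",
            right_index=True)
        prog = gt.gene_programs
        links = links[prog.loc[links["gene_id"]].to_numpy() == "ad_induced"]
        ch = enhancer_change(enh, "DNase", "3dOb")
        more = ch.loc[links.loc[links["response"] == "more", "enhancer_id"]]
        less = ch.loc[links.loc[links["response"] == "less", "enhancer_id"]]
        assert ks_2samp(more.to_numpy()[:200], less.to_numpy()[:200]).pvalue > 0.01

    def test_bed_bytes_deterministic(self, tmp_path):
        from transplast import io as tio

        cfg = small_cfg(seed=9)
        _, gt = synth.generate_sc_experiment(cfg)
        for name in ("a", "b"):
            enh, _ = synth.generate_enhancer_landscape(cfg, gt)
            tio.write_bed_enhancers(enh, tmp_path / f"{name}.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()
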