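"""Enhancer-gene linking, response classification, and effect sizes."""

import numpy as np
import pandas as pd
import pytest

from transplast import enhancers, evaluation
from transplast.io import EnhancerTable, TssTable


def _enh(rows):
    return EnhancerTable(pd.DataFrame(rows))


def _tss(rows):
    return TssTable(pd.DataFrame(rows))


class TestLinkEnhancers:
    def test_nearest_gene_wins(self):
        enh = _enh([{"chrom": "chrS", "start": 1400, "end": 1600,
                     "enhancer_id": "e1"}])
        tss = _tss([{"gene_id": "near", "chrom": "chrS", "tss_pos": 1000,
                     "strand": "+"},
                    {"gene_id": "far", "chrom": "chrS", "tss_pos": 5000,
                     "strand": "+"}])
        links = enhancers.link_enhancers(enh, tss)
        assert links.loc[0, "gene_id"] == "near"
        assert links.loc[0, "distance"] == 500.0

    def test_tie_breaks_to_smaller_tss(self):
        enh = _enh([{"chrom": "chrS", "start": 1400, "end": 1600,
                     "enhancer_id": "e1"}])
        tss = _tss([{"gene_id": "b", "chrom": "chrS", "tss_pos": 2000, "strand": "+"},
                    {"gene_id": "a", "chrom": "chrS", "tss_pos": 1000, "strand": "+"}])
        links = enhancers.link_enhancers(enh, tss)
        assert links.loc[0, "gene_id"] == "a"
        assert links.loc[0, "tie"]

    def test_no_cross_chromosome_link(self):
        enh = _enh([{"chrom": "chrX", "start": 0, "end": 10, "enhancer_id": "e1"}])
        tss = _tss([{"gene_id": "g", "chrom": "chrS", "tss_pos": 5, "strand": "+"}])
        links = enhancers.link_enhancers(enh, tss)
        assert pd.isna(links.loc[0, "gene_id"])

    def test_matches_brute_force_on_random_genomes(self):
        assert evaluation.linking_oracle_agreement(seed=3, n_genomes=25) == 1.0


class TestClassifyInduced:
    def _de(self, rows):
        return pd.DataFrame(rows)

    def test_rule_corners(self):
        genes = [f"g{i}" for i in range(8)]
        target = self._de({
            "gene_id": genes,
            "padj": [0.005, 0.005, 0.005, 0.05, 0.005, np.nan, 0.009, 0.005],
            "log2fc": [1.2, 1.2, -1.2, 1.2, 1.2, 1.0, 0.0, 2.0],
        })
        opposing = self._de({
            "gene_id": genes,
            "padj": [0.03, 0.03, 0.03, 0.03, 0.06, 0.03, 0.03, np.nan],
            "log2fc": [0.4, -0.4, 0.4, 0.4, 0.4, 0.4, 0.4, 0.4],
        })
        cls = enhancers.classify_induced(target, opposing).set_index(
            pd.Index(genes))
        assert cls.loc["g0", "commonality"] == "Common"
        assert cls.loc["g1", "commonality"] == "Spec"  # opposing lfc < 0
        assert not cls.loc["g2", "induced"]            # target lfc < 0
        assert not cls.loc["g3", "induced"]            # padj not < 0.01
        assert cls.loc["g4", "commonality"] == "Spec"  # opposing padj not < 0.05
        assert not cls.loc["g5", "induced"]            # NA padj
        assert not cls.loc["g6", "induced"]            # lfc == 0
        assert cls.loc["g7", "commonality"] == "Spec"  # opposing padj NA

    def test_threshold_monotonicity(self, rng):
        genes = [f"g{i}" for i in range(100)]
        target = self._de({"gene_id": genes,
                           "padj": rng.uniform(0, 0.02, 100),
                           "log2fc": rng.normal(1, 0.5, 100)})
        opposing = self._de({"gene_id": genes,
                             "padj": rng.uniform(0, 0.2, 100),
                             "log2fc": rng.normal(0.5, 0.5, 100)})
        tight = enhancers.classify_induced(target, opposing, alpha_common=0.05)
        loose = enhancers.classify_induced(target, opposing, alpha_common=0.10)
        was_common = tight["commonality"] == "Common"
        still_common = loose["commonality"] == "Common"
        assert (still_common | ~was_common).all()


class TestKmeansResponse:
    def test_planted_archetype_recovery(self):
        assert evaluation.kmeans_archetype_recovery(seed=2) >= 0.9

    def test_duplicated_rows_same_label(self, rng):
        prof = pd.DataFrame(rng.normal(size=(30, 3)),
                            columns=["MSC", "d", "s"],
                            index=[f"g{i}" for i in range(30)])
        prof.loc["g1"] = prof.loc["g0"]
        labels = enhancers.kmeans_response(prof, seed=0)
        assert labels["g0"] == labels["g1"]

    def test_seed_determinism(self, rng):
        prof = pd.DataFrame(rng.normal(size=(50, 3)),
                            columns=["MSC", "d", "s"],
                            index=[f"g{i}" for i in range(50)])
        l1 = enhancers.kmeans_response(prof, seed=4)
        l2 = enhancers.kmeans_response(prof, seed=4)
        assert l1.equals(l2)

    def test_too_few_genes_rejected(self):
        prof = pd.DataFrame([[0, 1, 2]], columns=["a", "b", "c"], index=["g"])
        with pytest.raises(ValueError, match="genes"):
            enhancers.kmeans_response(prof)


class TestEnhancerChange:
    def _table(self):
        return _enh([{"chrom": "chrS", "start": 0, "end": 10, "enhancer_id": "e1",
                      "DNase_MSC": 1.0, "DNase_3dOb": 3.0,
                      "MED1_MSC": 0.0, "MED1_3dOb": 0.0}])

    def test_hand_arithmetic(self):
        ch = enhancers.enhancer_change(self._table(), "DNase", "3dOb")
        assert ch["e1"] == pytest.approx(1.0)  # log2(4/2)

    def test_zero_tags_give_zero_change(self):
        ch = enhancers.enhancer_change(self._table(), "MED1", "3dOb")
        assert ch["e1"] == 0.0

    def test_precomputed_fold_change_passthrough(self):
        t = self._table().table.assign(DNase_log2fc_3dOb=0.75)
        ch = enhancers.enhancer_change(EnhancerTable(t), "DNase", "3dOb")
        assert ch["e1"] == 0.75

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="column"):
            enhancers.enhancer_change(self._table(), "H3K27ac", "3dOb")


class TestCohensD:
    def test_hand_computation(self):
        assert enhancers.cohens_d([1, 2, 3], [3, 4, 5]) == pytest.approx(-2.0)

    def test_identical_groups_zero(self):
        assert enhancers.cohens_d([2, 2, 2, 2], [2, 2, 2, 2]) == 0.0

    def test_large_sample_recovery(self, rng):
        a = rng.normal(0.5, 1.0, 2000)
        b = rng.normal(0.0, 1.0, 2000)
        assert enhancers.cohens_d(a, b) == pytest.approx(0.5, abs=0.05)

    def test_effect_sizes_table(self):
        vals = pd.Series([1, 2, 3, 3, 4, 5, 2, 2],
                         index=[f"e{i}" for i in range(8)], dtype=float)
        grp = pd.Series(["more"] * 3 + ["less"] * 3 + ["similar"] * 2,
                        index=vals.index)
        rep = enhancers.effect_sizes(vals, grp, [("more", "less")])
        assert rep.loc[0, "cohens_d"] == pytest.approx(-2.0)
        assert rep.loc[0, "n_a"] == 3

    def test_med1_filter(self):
        t = _enh([
            {"chrom": "chrS", "start": 0, "end": 10, "enhancer_id": "e1",
             "MED1_MSC": 0.0, "MED1_3dOb": 0.0, "MED1_3dAd": 0.0},
            {"chrom": "chrS", "start": 20, "end": 30, "enhancer_id": "e2",
             "MED1_MSC": 0.0, "MED1_3dOb": 2.0, "MED1_3dAd": 0.0},
        ])
        kept = enhancers.filter_med1_bound(t)
        assert list(kept.table["enhancer_id"]) == ["e2"]
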