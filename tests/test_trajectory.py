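"""Pseudotime inference, spline LRT, binning, and trajectory comparison."""

import numpy as np
import pandas as pd
import pytest

from transplast import evaluation, synth, trajectory
from transplast.io import CountMatrix
from transplast.trajectory import (
    PseudotimeAssignment,
    bin_along_pseudotime,
    cross_condition_correlation,
    group_by_significance,
    natural_spline_basis,
)


class TestInferPseudotime:
    def test_recovers_planted_ordering(self):
        rho = evaluation.pseudotime_recovery(seed=11)
        assert rho >= 0.95

    def test_reversed_root_flips_ordering(self):
        rho = evaluation.pseudotime_recovery(seed=11, reverse=True)
        assert rho <= -0.95

    def test_duplicate_cells_get_identical_t(self, rng):
        vals = rng.integers(0, 30, size=(100, 60))
        # duplicate five non-root cells within the same library
        vals = np.concatenate([vals, vals[:, 20:25]], axis=1)
        genes = np.array([f"g{i}" for i in range(100)], dtype=object)
        cells = np.array([f"c{j}" for j in range(65)], dtype=object)
        labels = pd.Series(["root"] * 10 + ["rest"] * 55, index=cells)
        m = CountMatrix(vals, genes, cells)
        pt = trajectory.infer_pseudotime(m, "root", labels=labels, k=5, seed=0)
        for j in range(5):
            assert pt.t[f"c{60 + j}"] == pytest.approx(pt.t[f"c{20 + j}"], abs=1e-9)

    def test_missing_root_rejected(self, rng):
        vals = rng.integers(0, 30, size=(50, 40))
        m = CountMatrix(vals, np.array([f"g{i}" for i in range(50)], dtype=object),
                        np.array([f"c{j}" for j in range(40)], dtype=object))
        labels = pd.Series(["x"] * 40, index=m.unit_ids)
        with pytest.raises(ValueError, match="labelled"):
            trajectory.infer_pseudotime(m, "nope", labels=labels)


class TestSplineBasis:
    def test_shape_and_linearity(self):
        x = np.linspace(0, 1, 50)
        b = natural_spline_basis(x, df=3)
        assert b.shape == (50, 3)
        assert np.allclose(b[:, 0], x)

    def test_constant_x_degenerates_gracefully(self):
        b = natural_spline_basis(np.full(30, 0.5), df=3)
        assert b.shape == (30, 3)


class TestPseudotimeDe:
    def test_calibration_on_null(self):
        assert 0.03 <= evaluation.ptde_calibration(seed=13) <= 0.07

    def test_power_on_planted_sigmoid(self):
        assert evaluation.ptde_power(seed=14) >= 0.9

    def test_low_fraction_gene_excluded(self, rng):
        n = 200
        t = pd.Series(np.linspace(0, 1, n),
                      index=pd.Index([f"c{i}" for i in range(n)], name="cell_id"),
                      name="t")
        vals = rng.poisson(5.0, size=(2, n))
        vals[0] = 0
        vals[0, :18] = 50  # expressed in 9% of cells, strongly dynamic
        m = CountMatrix(vals, np.array(["sparse", "dense"], dtype=object),
                        np.asarray(t.index, dtype=object))
        res = trajectory.pseudotime_de(m, PseudotimeAssignment(t, "", []))
        res = res.set_index("gene_id")
        assert np.isnan(res.loc["sparse", "p"])
        assert not res.loc["sparse", "significant"]

    def test_too_few_cells_rejected(self, rng):
        t = pd.Series(np.linspace(0, 1, 20),
                      index=pd.Index([f"c{i}" for i in range(20)]), name="t")
        m = CountMatrix(rng.poisson(5, size=(5, 20)),
                        np.array([f"g{i}" for i in range(5)], dtype=object),
                        np.asarray(t.index, dtype=object))
        with pytest.raises(ValueError, match="cells"):
            trajectory.pseudotime_de(m, PseudotimeAssignment(t, "", []))


def _profile_frame(values, cells):
    return pd.DataFrame(values, index=["gA"], columns=cells)


class TestBinning:
    def _pt(self, t_values, cells):
        t = pd.Series(t_values, index=pd.Index(cells, name="cell_id"), name="t")
        return PseudotimeAssignment(t, "", [])

    def test_ten_cells_five_even_bins(self):
        cells = [f"c{i}" for i in range(10)]
        pt = self._pt(np.linspace(0, 1, 10), cells)
        prof = bin_along_pseudotime(_profile_frame([range(10)], cells), pt, 5)
        assert list(prof.occupancy) == [2, 2, 2, 2, 2]

    def test_remainder_goes_to_early_bins(self):
        cells = [f"c{i}" for i in range(11)]
        pt = self._pt(np.linspace(0, 1, 11), cells)
        prof = bin_along_pseudotime(_profile_frame([range(11)], cells), pt, 5)
        assert list(prof.occupancy) == [3, 2, 2, 2, 2]

    def test_identity_gene_monotone(self):
        cells = [f"c{i}" for i in range(40)]
        t = np.linspace(0, 1, 40)
        pt = self._pt(t, cells)
        prof = bin_along_pseudotime(_profile_frame([t], cells), pt, 8)
        assert (np.diff(prof.means.loc["gA"]) > 0).all()

    def test_cell_order_invariance_with_tie_break(self, rng):
        cells = [f"c{i}" for i in range(30)]
        t = np.round(rng.uniform(0, 1, 30), 1)  # many ties
        vals = rng.normal(size=(1, 30))
        pt = self._pt(t, cells)
        prof1 = bin_along_pseudotime(_profile_frame(vals, cells), pt, 6)
        perm = rng.permutation(30)
        frame2 = _profile_frame(vals[:, perm], [cells[i] for i in perm])
        prof2 = bin_along_pseudotime(frame2, pt, 6)
        assert np.allclose(prof1.means.to_numpy(), prof2.means.to_numpy())

    def test_too_many_bins_rejected(self):
        cells = [f"c{i}" for i in range(4)]
        pt = self._pt([0, 0.2, 0.6, 1.0], cells)
        with pytest.raises(ValueError, match="bins"):
            bin_along_pseudotime(_profile_frame([range(4)], cells), pt, 5)


class TestCrossConditionCorrelation:
    def _profiles(self, rng, n_genes=10, n_bins=20):
        vals = rng.normal(size=(n_genes, n_bins))
        means = pd.DataFrame(vals, index=[f"g{i}" for i in range(n_genes)])
        return trajectory.BinnedProfile("A", n_bins, means,
                                        np.ones(n_bins, int), np.linspace(0, 1, n_bins))

    def test_self_correlation_is_one(self, rng):
        a = self._profiles(rng)
        r = cross_condition_correlation(a, a)
        assert np.allclose(r.dropna(), 1.0)

    def test_negated_profile_is_minus_one(self, rng):
        a = self._profiles(rng)
        b = trajectory.BinnedProfile("B", a.n_bins, -a.means, a.occupancy, a.bin_t)
        assert np.allclose(cross_condition_correlation(a, b).dropna(), -1.0)

    def test_affine_invariance_and_symmetry(self, rng):
        a, b = self._profiles(rng), self._profiles(rng)
        r_ab = cross_condition_correlation(a, b).sort_index()
        r_ba = cross_condition_correlation(b, a).sort_index()
        assert np.allclose(r_ab, r_ba)
        shifted = trajectory.BinnedProfile("B2", b.n_bins, 3.0 * b.means + 7.0,
                                           b.occupancy, b.bin_t)
        r2 = cross_condition_correlation(a, shifted).sort_index()
        assert np.allclose(r_ab, r2)

    def test_zero_variance_gene_is_na_and_last(self, rng):
        a = self._profiles(rng, n_genes=3)
        b_vals = a.means.copy()
        b_vals.iloc[1] = 5.0
        b = trajectory.BinnedProfile("B", a.n_bins, b_vals, a.occupancy, a.bin_t)
        r = cross_condition_correlation(a, b)
        assert np.isnan(r.iloc[-1])

    def test_too_few_bins_rejected(self, rng):
        a = self._profiles(rng, n_bins=2)
        with pytest.raises(ValueError, match="bins"):
            cross_condition_correlation(a, a)


class TestGroupBySignificance:
    def test_enumerated_toy_universe(self):
        flags = [(True, False), (False, True), (True, True),
                 (False, False), (True, True), (False, True)]
        genes = [f"g{i}" for i in range(6)]
        de_a = pd.DataFrame({"gene_id": genes, "significant": [f[0] for f in flags]})
        de_b = pd.DataFrame({"gene_id": genes, "significant": [f[1] for f in flags]})
        grp = group_by_significance(de_a, de_b)
        counts = grp["group"].value_counts()
        assert counts["direct_only"] == 1
        assert counts["switch_only"] == 2
        assert counts["both"] == 2
        assert "g3" not in grp.index  # significant in neither -> excluded


class TestConcordance:
    def test_shared_programs_correlate_and_groups_match(self):
        """Direct and trans-differentiation arms sharing the osteogenic
        program give highly correlated binned trajectories (small n here;
        the full-scale check lives in the acceptance suite)."""
        r = evaluation.trajectory_concordance(seed=7, n_cells=800)
        assert r > 0.8
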