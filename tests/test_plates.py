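import numpy as np
import pandas as pd
import pytest
from scipy import stats

import endophen as ep
from endophen.plates import dbcamp_dose, load_plate_layout


class TestRelativeAbsorbance:
    @pytest.mark.parametrize("a590,a750,expected", [(1.20, 0.20, 1.00), (0.50, 0.50, 0.00)])
    def test_arithmetic(self, a590, a750, expected):
        assert ep.relative_absorbance(a590, a750) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ep.relative_absorbance(-0.1, 0.0)

    def test_plate_equals_elementwise_subtraction(self, rng):
        a590 = rng.uniform(0, 2, size=96)
        a750 = rng.uniform(0, 0.3, size=96)
        out = ep.relative_absorbance(a590, a750)
        for i in range(96):  # oracle loop
            assert out[i] == a590[i] - a750[i]

    def test_linear_and_order_preserving(self, rng):
        a = rng.uniform(0, 1, 10)
        b = rng.uniform(0, 0.2, 10)
        out = ep.relative_absorbance(a, b)
        assert np.allclose(
            ep.relative_absorbance(2 * a, 2 * b), 2 * out
        )
        order = np.argsort(a)
        assert (np.diff(out[order] + b[order]) >= 0).all()


class TestLayouts:
    def test_all_layouts_have_96_wells(self):
        for pid in ("PM-M1", "PM-M2", "PM-M3", "PM-M4", "PM-M6"):
            assert len(load_plate_layout(pid)) == 96

    def test_pm_m6_row_a_is_dose_series(self):
        lay = load_plate_layout("PM-M6")
        doses = [dbcamp_dose(lay[f"A{i}"]) for i in range(1, 13)]
        assert doses[0] == 0.0
        assert all(d is not None for d in doses)
        assert doses == sorted(doses)


class TestFilterBackground:
    @staticmethod
    def profiles(shift, n_cells=10, n_blanks=5, seed=0):
        rng = np.random.default_rng(seed)
        compounds = [f"c{i}" for i in range(5)]
        cells = [
            ep.MetabolicProfile(
                f"cl{i}", "TD", "none",
                pd.Series(rng.normal(0.1 + shift, 0.02, 5), index=compounds),
            )
            for i in range(n_cells)
        ]
        blanks = [
            ep.MetabolicProfile(
                f"b{i}", "blank", "none",
                pd.Series(rng.normal(0.1, 0.02, 5), index=compounds),
            )
            for i in range(n_blanks)
        ]
        return cells, blanks

    def test_null_compounds_removed(self):
        cells, blanks = self.profiles(shift=0.0)
        kept, _ = ep.filter_background(cells, blanks)
        assert len(kept) <= 1  # at alpha=0.05 almost everything fails

    def test_shifted_compounds_kept(self):
        cells, blanks = self.profiles(shift=0.2)  # +10 blank SDs
        kept, pv = ep.filter_background(cells, blanks)
        assert len(kept) == 5
        assert (pv < 1e-4).all()

    def test_missing_blanks_rejected(self):
        cells, blanks = self.profiles(shift=0.1)
        with pytest.raises(ValueError, match="blank"):
            ep.filter_background(cells, blanks[:1])


class TestAnovaTukey:
    def test_identical_groups_f_zero(self):
        vals = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [1.0, 2.0, 3.0]}
        res = ep.anova_tukey(vals)
        assert res.f_statistic == pytest.approx(0.0)

    def test_two_groups_tukey_equals_anova_p(self, rng):
        vals = {"a": rng.normal(0, 1, 8), "b": rng.normal(0.5, 1, 8)}
        res = ep.anova_tukey(vals)
        assert res.pairwise["p_adj"].iloc[0] == pytest.approx(res.p_value, rel=1e-4)

    def test_matches_r_tukeyhsd_oracle(self):
        # frozen reference computed with R stats::aov + TukeyHSD on this table
        vals = {
            "a": [1.1, 0.9, 1.3, 1.0, 1.2],
            "b": [1.8, 2.1, 1.9, 2.2, 2.0],
            "c": [1.2, 1.4, 1.0, 1.3, 1.1],
        }
        res = ep.anova_tukey(vals)
        assert res.f_statistic == pytest.approx(48.6667, rel=1e-4)
        assert res.p_value == pytest.approx(1.75e-6, rel=0.01)
        expected = {("a", "b"): 3.075810e-06, ("a", "c"): 0.590770608, ("b", "c"): 1.0433142e-05}
        for _, row in res.pairwise.iterrows():
            assert row["p_adj"] == pytest.approx(expected[(row["group1"], row["group2"])], rel=1e-4)

    def test_studentized_range_assembly(self):
        """Independent Tukey computation from the studentized-range distribution."""
        vals = {
            "a": [1.1, 0.9, 1.3, 1.0, 1.2],
            "b": [1.8, 2.1, 1.9, 2.2, 2.0],
            "c": [1.2, 1.4, 1.0, 1.3, 1.1],
        }
        res = ep.anova_tukey(vals)
        arrays = [np.array(v) for v in vals.values()]
        n = 5
        k = 3
        mse = np.sum([(a - a.mean()) ** 2 for a in arrays]) / (k * (n - 1))
        q = abs(arrays[0].mean() - arrays[1].mean()) / np.sqrt(mse / n)
        p_ab = stats.studentized_range.sf(q, k, k * (n - 1))
        assert res.pairwise.set_index(["group1", "group2"]).loc[("a", "b"), "p_adj"] == pytest.approx(p_ab, rel=1e-6)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            ep.anova_tukey({"a": [1.0], "b": [1.0, 2.0]})


class TestPCAMetabolic:
    def test_single_axis_variance(self, rng):
        t = rng.normal(size=20)
        mat = pd.DataFrame({"x": t, "y": 2 * t, "z": -t})
        res = ep.pca_metabolic(mat, scale=False)
        assert res.variance_explained[0] == pytest.approx(1.0)

    def test_contributions_sum_to_one(self, rng):
        mat = pd.DataFrame(rng.normal(size=(15, 6)))
        res = ep.pca_metabolic(mat)
        assert np.allclose(res.contributions.sum(axis=0), 1.0)

    def test_reconstruction(self, rng):
        mat = pd.DataFrame(rng.normal(size=(10, 4)))
        res = ep.pca_metabolic(mat, scale=False)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        centred = mat.to_numpy() - mat.to_numpy().mean(axis=0)
        assert np.allclose(recon, centred, atol=1e-10)

    def test_variance_explained_monotone(self, rng):
        mat = pd.DataFrame(rng.normal(size=(12, 8)))
        res = ep.pca_metabolic(mat)
        assert (np.diff(res.variance_explained) <= 1e-12).all()
        assert res.variance_explained.sum() <= 1 + 1e-9

    def test_planted_orthogonal_structure_lands_on_dim2(self):
        """A Phen1-only nucleoside shift orthogonal to a shared sugar axis is
        recovered as the top dim-2 contributions."""
        sugars = [
            "D-glucose-6-phosphate", "D-glucose-1-phosphate", "D-glucose",
            "D-mannose", "D-fructose-6-phosphate", "D-galactose",
        ]
        nucleosides = ["adenosine", "inosine", "mono-methyl succinate"]
        effects = {c: {"Phen1": -0.3, "nonPhen1": -0.3} for c in sugars}
        effects.update({c: {"Phen1": 0.25} for c in nucleosides})
        hits = 0
        for seed in range(3):
            cfg = ep.PlateSimConfig(
                compound_effects=effects, plates=("PM-M1",), seed=seed,
                well_sd=0.03,
            )
            profs = [
                ep.profile_from_assay(a)
                for a in ep.gen_plates(cfg)
                if a.group != "blank"
            ]
            mat = pd.DataFrame({p.cell_line_id: p.values for p in profs}).T
            res = ep.pca_metabolic(mat, scale=False)
            top3 = set(res.contributions["dim2"].nlargest(3).index)
            hits += top3 == set(nucleosides)
        assert hits >= 2

    def test_missing_values_rejected(self):
        mat = pd.DataFrame([[1.0, np.nan], [2.0, 3.0], [0.0, 1.0]])
        with pytest.raises(ValueError, match="missing"):
            ep.pca_metabolic(mat)


class TestDoseResponse:
    def test_zero_dose_normalises_to_one(self):
        series = [(0, 2.0), (1, 2.4), (2, 3.0)]
        dr = ep.dose_response(series)
        assert dr.curve.loc[dr.curve["dose"] == 0, "normalized"].iloc[0] == 1.0

    def test_flat_series_not_significant(self, rng):
        series = [(d, 1.0 + rng.normal(0, 0.05)) for d in [0, 1, 2, 5] for _ in range(6)]
        dr = ep.dose_response(series)
        assert dr.p_trend > 0.01

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            ep.dose_response([(0, 0.0), (1, 1.0)])

    def test_phen1_only_slope_detected_only_in_phen1(self):
        detected = {}
        for seed in range(3):
            assays = ep.gen_plates(
                ep.PlateSimConfig(
                    seed=seed,
                    plates=("PM-M6",),
                    group_sizes={"TD": 10, "nonPhen1": 10, "Phen1": 10},
                )
            )
            for grp in ["TD", "nonPhen1", "Phen1"]:
                series = [
                    (dbcamp_dose(c), a590 - a750)
                    for a in assays
                    if a.group == grp
                    for _, (c, a590, a750) in a.wells.items()
                    if dbcamp_dose(c) is not None
                ]
                detected.setdefault(grp, []).append(
                    ep.dose_response(series).p_trend < 0.01
                )
        assert all(detected["Phen1"])
        assert sum(detected["TD"]) + sum(detected["nonPhen1"]) <= 1
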