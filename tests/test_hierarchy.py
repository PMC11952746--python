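"""fILN statistic, dominance, rankings, and interhemispheric analyses."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import projectome as pj

fractions3 = st.tuples(
    st.floats(0, 1), st.floats(0, 1), st.floats(0, 1)
).filter(lambda t: sum(t) > 0)


class TestFiln:
    def test_hand_arithmetic_default(self):
        assert pj.filn({"L2/3": 0.30, "L5": 0.30, "L6": 0.40}) == pytest.approx(0.70)

    def test_no_supragranular_input_is_pure_feedback(self):
        assert pj.filn({"L2/3": 0.0, "L5": 0.4, "L6": 0.1}) == 1.0

    def test_variants_from_raw_counts(self):
        counts = {"L2/3": 20, "L5": 30, "L6": 50}
        assert pj.filn(counts, "default") == pytest.approx(0.8)
        assert pj.filn(counts, "excl_L6") == pytest.approx(0.6)
        assert pj.filn(counts, "excl_L5") == pytest.approx(50 / 70)

    def test_l6a_key_accepted(self):
        assert pj.filn({"L2/3": 1, "L5": 1, "L6a": 2}) == pytest.approx(0.75)

    def test_empty_denominator_undefined(self):
        assert math.isnan(pj.filn({"L2/3": 0, "L5": 0, "L6": 0}))
        # variant denominator can vanish even when the default is defined
        assert math.isnan(pj.filn({"L2/3": 0, "L5": 1, "L6": 0}, "excl_L5"))

    def test_negative_fraction_rejected(self):
        with pytest.raises(ValueError):
            pj.filn({"L2/3": -0.1, "L5": 0.5, "L6": 0.6})

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            pj.filn({"L2/3": 1, "L5": 1, "L6": 1}, "excl_L23")

    @settings(max_examples=200, deadline=None)
    @given(profile=fractions3)
    def test_bounds_and_ablation_monotonicity(self, profile):
        l23, l5, l6 = profile
        p = {"L2/3": l23, "L5": l5, "L6": l6}
        default = pj.filn(p)
        assert 0.0 <= default <= 1.0
        if l23 == 0:
            assert default == 1.0
        if l5 == 0 and l6 == 0:
            assert default == 0.0
        for variant in ("excl_L5", "excl_L6"):
            v = pj.filn(p, variant)
            if not math.isnan(v):
                assert default >= v - 1e-12


class TestFilnTable:
    def test_pooled_equals_filn_of_summed_counts(self, visp_sim):
        _, cohort, _ = visp_sim
        filtered = pj.filter_cohort(cohort)
        pooled = pj.pooled_filn(filtered, prefiltered=True)
        animal = filtered.animals[0]
        df = animal.counts
        keep = ~((df["hemisphere"] == "ipsi") & (df["area"] == "VISp"))
        sums = df[keep].groupby(["hemisphere", "layer"])["count"].sum()
        expected = pj.filn(
            {
                "L2/3": sums.get(("contra", "L2/3"), 0),
                "L5": sums.get(("contra", "L5"), 0),
                "L6": sums.get(("contra", "L6a"), 0),
            }
        )
        got = pooled[
            (pooled["animal_id"] == animal.animal_id)
            & (pooled["hemisphere"] == "contra")
        ]["filn"].iloc[0]
        assert got == pytest.approx(expected)

    def test_all_supragranular_empty_gives_filn_one(self, make_animal):
        animals = tuple(
            make_animal(
                [("ipsi", "VISl", "L5", 30), ("ipsi", "VISl", "L6a", 70)],
                animal_id=f"m{i}",
            )
            for i in range(3)
        )
        tab = pj.filn_table(pj.CohortData("VISp", animals))
        defined = tab.dropna(subset=["filn"])
        assert not defined.empty
        assert (defined["filn"] == 1.0).all()

    def test_target_area_ipsi_always_undefined(self, visp_sim):
        _, cohort, _ = visp_sim
        tab = pj.filn_table(cohort)
        target_ipsi = tab[(tab["area"] == "VISp") & (tab["hemisphere"] == "ipsi")]
        assert target_ipsi["filn"].isna().all()
        target_contra = tab[(tab["area"] == "VISp") & (tab["hemisphere"] == "contra")]
        assert target_contra["filn"].notna().any()  # homotopic input retained


class TestDominance:
    def test_argmax(self):
        assert pj.dominance({"L2/3": 0.5, "L5": 0.3, "L6": 0.2}) == "L2/3"

    def test_tie_breaks_toward_deeper_layer(self):
        assert pj.dominance({"L2/3": 0.2, "L5": 0.4, "L6": 0.4}) == "L6"
        assert pj.dominance({"L2/3": 0.4, "L5": 0.4, "L6": 0.2}) == "L5"

    def test_l6_pools_sublayers(self):
        assert pj.dominance({"L2/3": 0.39, "L5": 0.25, "L6a": 0.20, "L6b": 0.20}) == "L6"

    def test_empty_profile_undefined(self):
        assert pj.dominance({"L2/3": 0, "L5": 0, "L6": 0}) is None

    def test_constructed_tally(self, make_animal, atlas):
        # 10 areas, 6 with L6-dominant profiles and 4 with L2/3-dominant ones
        areas = [a for a in atlas.acronyms if a != "VISp"][:10]
        animals = []
        for i in range(3):
            rows = []
            for j, area in enumerate(areas):
                if j < 6:
                    rows += [("ipsi", area, "L6a", 80), ("ipsi", area, "L2/3", 20)]
                else:
                    rows += [("ipsi", area, "L2/3", 80), ("ipsi", area, "L6a", 20)]
            animals.append(make_animal(rows, animal_id=f"m{i}"))
        cohort = pj.CohortData("VISp", tuple(animals))
        labels = pj.dominance_table(cohort, basis="per_animal")
        tally = pj.dominance_tally(labels)
        l6 = tally[(tally["label"] == "L6")]
        assert np.allclose(l6["percent"], 60.0)

    def test_cohort_average_basis_labels_mean_profile(self, visp_sim):
        _, cohort, _ = visp_sim
        labels = pj.dominance_table(cohort, basis="cohort_average")
        assert set(labels["basis"]) == {"cohort_average"}
        assert "animal_id" not in labels.columns
        assert labels["label"].dropna().isin(["L2/3", "L5", "L6"]).all()


class TestRanking:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["animal_id", "hemisphere", "area", "filn"])

    def test_ascending_order(self, atlas):
        tab = self._table(
            [("m1", "ipsi", "VISl", 0.9), ("m1", "ipsi", "VISal", 0.4),
             ("m1", "ipsi", "MOs", 0.6)]
        )
        ranked = pj.rank_areas(tab, "ipsi", atlas)
        assert list(ranked["area"]) == ["VISal", "MOs", "VISl"]
        assert list(ranked["rank"]) == [1, 2, 3]

    def test_nan_aware_mean_counts_contributors(self, atlas):
        tab = self._table(
            [("m1", "ipsi", "VISl", 0.4), ("m2", "ipsi", "VISl", np.nan),
             ("m3", "ipsi", "VISl", 0.8)]
        )
        ranked = pj.rank_areas(tab, "ipsi", atlas)
        assert ranked.loc[0, "mean_filn"] == pytest.approx(0.6)
        assert ranked.loc[0, "n"] == 2

    def test_ties_break_by_area_index(self, atlas):
        # VISal (index 27) before VISl (index 29) at equal means
        tab = self._table(
            [("m1", "ipsi", "VISl", 0.5), ("m1", "ipsi", "VISal", 0.5)]
        )
        ranked = pj.rank_areas(tab, "ipsi", atlas)
        assert list(ranked["area"]) == ["VISal", "VISl"]

    def test_area_with_no_defined_values_dropped_with_warning(self, atlas):
        tab = self._table(
            [("m1", "ipsi", "VISl", 0.5), ("m1", "ipsi", "VISal", np.nan)]
        )
        with pytest.warns(UserWarning, match="VISal"):
            ranked = pj.rank_areas(tab, "ipsi", atlas)
        assert list(ranked["area"]) == ["VISl"]


class TestInterhemisphericDelta:
    def _table(self, ipsi, contra):
        rows = [("m1", "ipsi", "VISl", ipsi), ("m1", "contra", "VISl", contra)]
        return pd.DataFrame(rows, columns=["animal_id", "hemisphere", "area", "filn"])

    def test_equal_hemispheres_give_zero(self):
        out = pj.interhemispheric_delta(self._table(0.5, 0.5))
        assert out["delta"].iloc[0] == 0.0

    def test_hand_arithmetic(self):
        out = pj.interhemispheric_delta(self._table(0.42, 0.66))
        assert out["delta"].iloc[0] == pytest.approx(0.24)

    def test_nan_propagates(self):
        out = pj.interhemispheric_delta(self._table(np.nan, 0.66))
        assert math.isnan(out["delta"].iloc[0])


class TestModuleFiln:
    def test_constant_member_areas(self, atlas):
        rows = [
            ("m1", "ipsi", a, 0.8) for a in atlas.areas_in_module("visual")
        ]
        tab = pd.DataFrame(rows, columns=["animal_id", "hemisphere", "area", "filn"])
        out = pj.module_filn(tab, atlas, "modules")
        vis = out[out["unit"] == "visual"]
        assert vis["mean_filn"].iloc[0] == pytest.approx(0.8)

    def test_group_mean_equals_concatenated_member_mean(self, visp_sim, atlas):
        _, cohort, _ = visp_sim
        tab = pj.filn_table(cohort)
        out = pj.module_filn(tab, atlas, "groups")
        vasm = set(atlas.areas_in_group("v-a-sm"))
        animal = cohort.animals[0].animal_id
        sub = tab[
            (tab["animal_id"] == animal)
            & (tab["hemisphere"] == "ipsi")
            & tab["area"].isin(vasm)
        ]
        expected = sub["filn"].mean()
        got = out[
            (out["animal_id"] == animal)
            & (out["hemisphere"] == "ipsi")
            & (out["unit"] == "v-a-sm")
        ]["mean_filn"].iloc[0]
        assert got == pytest.approx(expected)


class TestLaminarChange:
    def _mirrored_cohort(self, make_animal, atlas, n=4, boost=None):
        vasm = [a for a in atlas.areas_in_group("v-a-sm") if a != "VISp"][:8]
        boosted = set(vasm[: len(vasm) // 2]) if boost else set()
        animals = []
        rng = np.random.default_rng(0)
        for i in range(n):
            rows = []
            for area in vasm:
                base = {"L2/3": 50, "L5": 30, "L6a": 20}
                jit = {k: int(v + rng.integers(0, 3)) for k, v in base.items()}
                for layer, c in jit.items():
                    rows.append(("ipsi", area, layer, c))
                contra = dict(jit)
                if area in boosted:
                    contra["L6a"] = contra["L6a"] * 4  # doubles its fraction
                for layer, c in contra.items():
                    rows.append(("contra", area, layer, c))
            animals.append(make_animal(rows, animal_id=f"m{i}"))
        return pj.CohortData("VISp", tuple(animals))

    def test_identical_hemispheres_show_no_change(self, make_animal, atlas):
        cohort = self._mirrored_cohort(make_animal, atlas)
        changes, tally = pj.laminar_change(cohort)
        tested = changes.dropna(subset=["p"])
        assert (tested["mean_change"].abs() < 1e-12).all()
        assert not tested["significant"].any()
        assert (tally["percent_of_areas"] == 0).all()

    def test_half_of_areas_boost_l6a(self, make_animal, atlas):
        cohort = self._mirrored_cohort(make_animal, atlas, n=6, boost=True)
        changes, tally = pj.laminar_change(cohort)
        l6_up = tally[
            (tally["layer"] == "L6a") & (tally["direction"] == "increase")
        ]["percent_of_areas"].iloc[0]
        assert l6_up == pytest.approx(50.0)

    def test_homotopic_target_area_excluded(self, visp_sim):
        _, cohort, _ = visp_sim
        changes, _ = pj.laminar_change(cohort)
        assert "VISp" not in set(changes["area"])


class TestFilnCorrelations:
    def test_recovers_monotone_relation(self, visp_sim):
        _, cohort, _ = visp_sim
        tab = pj.filn_table(cohort)
        ipsi_vs_contra, ipsi_vs_delta = pj.filn_correlations(tab)
        assert ipsi_vs_contra.method == "spearman"
        # contra profiles are a rank-preserving shift of ipsi ones
        assert ipsi_vs_contra.value > 0.5
        # delta shrinks as ipsi fILN rises (ceiling at 1): negative correlation
        assert ipsi_vs_delta.value < -0.5
        assert len(ipsi_vs_contra.per_animal_values) == 6
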