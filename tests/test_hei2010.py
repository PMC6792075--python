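import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dietshift as ds
from dietshift.hei2010 import COMPONENT_NAMES, STANDARDS, densities, hei_scores_frame


def oracle_component_score(value, standard):
    """Independent piecewise evaluation of an HEI-2010 standard: explicit
    branch logic rather than clipped interpolation."""
    if math.isnan(value):
        return 0.0
    z, m, pts = standard.value_at_zero, standard.value_at_max, standard.max_points
    if standard.direction == "adequacy":
        if value >= m:
            return pts
        if value <= z:
            return 0.0
        return pts * (value - z) / (m - z)
    # moderation: high values are bad
    if value <= m:
        return pts
    if value >= z:
        return 0.0
    return pts * (z - value) / (z - m)


def _ideal_day():
    """All adequacy densities at their max standards, all moderation values
    at or below theirs (per 2000 kcal)."""
    nv = ds.NutrientVector(energy=2000.0, sodium=2000.0)  # 1.0 g/1000 kcal
    gv = ds.FoodGroupVector(
        total_fruit=1.6, whole_fruit=0.8, total_veg=2.2, greens_beans=0.4,
        whole_grains=3.0, refined_grains=3.0, dairy=2.6, total_protein=5.0,
        seafood_plant_protein=1.6, mufa=20.0, pufa=10.0, sfa=10.0,
        added_sugar=0.0, solid_fat_kcal=0.0, alcohol=0.0,
    )
    return nv, gv


class TestDensities:
    def test_density_is_per_1000_kcal(self):
        d = densities(
            ds.NutrientVector(energy=1000.0), ds.FoodGroupVector(whole_grains=1.5)
        )
        assert d["whole_grains"] == pytest.approx(1.5)

    def test_sandwich1_only_day_whole_grain_density(self, profiles):
        p1 = profiles["Sandwich 1"]
        d = densities(p1.nutrients, p1.groups)
        assert d["whole_grains"] == pytest.approx(2 * 1000 / 437, rel=1e-4)

    def test_zero_sfa_with_unsaturated_fat_is_infinite_ratio(self):
        d = densities(
            ds.NutrientVector(energy=1000.0), ds.FoodGroupVector(mufa=5.0)
        )
        assert math.isinf(d["fatty_acids"])

    def test_zero_energy_flags_all_undefined(self):
        d = densities(ds.NutrientVector(), ds.FoodGroupVector(dairy=2.0))
        assert all(math.isnan(v) for v in d.values())

    def test_alcohol_below_threshold_adds_no_empty_calories(self):
        base = ds.FoodGroupVector(alcohol=13.0)
        d = densities(ds.NutrientVector(energy=1000.0), base)
        assert d["empty_calories"] == pytest.approx(0.0)
        over = ds.FoodGroupVector(alcohol=15.0)
        d2 = densities(ds.NutrientVector(energy=1000.0), over)
        assert d2["empty_calories"] == pytest.approx(7.0 * 2.0 * 100 / 1000.0)

    def test_added_sugar_counts_16_kcal_per_tsp(self):
        d = densities(
            ds.NutrientVector(energy=1600.0), ds.FoodGroupVector(added_sugar=10.0)
        )
        assert d["empty_calories"] == pytest.approx(160.0 * 100 / 1600.0)


class TestComponentScore:
    @pytest.mark.parametrize(
        "component,value,expected",
        [
            ("whole_grains", 0.75, 5.0),   # midpoint of the 0 -> 1.5 ramp
            ("sodium", 2.5, 0.0),          # beyond the zero-score standard
            ("fatty_acids", 2.5, 10.0),    # at the max standard
            ("sodium", 1.1, 10.0),
            ("empty_calories", 50.0, 0.0),
            ("empty_calories", 19.0, 20.0),
        ],
    )
    def test_standard_anchor_points(self, component, value, expected):
        assert ds.component_score(value, STANDARDS[component]) == pytest.approx(expected)

    def test_matches_independent_oracle_on_random_grid(self, rng):
        """Clipped-interpolation scoring agrees with an explicitly branched
        piecewise evaluator on 10,000 random values."""
        names = list(COMPONENT_NAMES)
        for _ in range(10_000 // len(names)):
            for name in names:
                std = STANDARDS[name]
                lo = min(std.value_at_zero, std.value_at_max)
                hi = max(std.value_at_zero, std.value_at_max)
                v = float(rng.uniform(lo - (hi - lo), hi + (hi - lo)))
                assert ds.component_score(v, std) == pytest.approx(
                    oracle_component_score(v, std), abs=1e-12
                )

    @given(st.floats(min_value=0.0, max_value=10.0), st.floats(min_value=0.0, max_value=10.0))
    @settings(max_examples=200, deadline=None)
    def test_adequacy_monotone_nondecreasing(self, a, b):
        std = STANDARDS["whole_grains"]
        lo, hi = sorted((a, b))
        assert ds.component_score(lo, std) <= ds.component_score(hi, std) + 1e-12

    @given(st.floats(min_value=0.0, max_value=10.0), st.floats(min_value=0.0, max_value=10.0))
    @settings(max_examples=200, deadline=None)
    def test_moderation_monotone_nonincreasing(self, a, b):
        std = STANDARDS["sodium"]
        lo, hi = sorted((a, b))
        assert ds.component_score(lo, std) + 1e-12 >= ds.component_score(hi, std)


class TestHeiScore:
    def test_zero_energy_scores_zero(self):
        res = ds.hei_score(ds.NutrientVector(), ds.FoodGroupVector(dairy=3.0))
        assert res.total == 0.0
        assert all(v == 0.0 for v in res.components.values())

    def test_ideal_day_scores_100(self):
        nv, gv = _ideal_day()
        res = ds.hei_score(nv, gv)
        assert res.total == pytest.approx(100.0)
        for name, score in res.components.items():
            assert score == pytest.approx(STANDARDS[name].max_points), name

    def test_all_midpoint_moderation_day_scores_75(self):
        """Adequacy components all maxed (50 pts) plus every moderation/
        ratio component at its ramp midpoint (5 + 5 + 5 + 10)."""
        nv = ds.NutrientVector(energy=1000.0, sodium=1550.0)
        gv = ds.FoodGroupVector(
            total_fruit=0.8, whole_fruit=0.4, total_veg=1.1, greens_beans=0.2,
            whole_grains=1.5, refined_grains=3.05, dairy=1.3, total_protein=2.5,
            seafood_plant_protein=0.8, mufa=1.233, pufa=0.617, sfa=1.0,
            solid_fat_kcal=345.0,
        )
        assert ds.hei_score(nv, gv).total == pytest.approx(75.0)

    def test_total_is_sum_of_components(self, rng):
        for _ in range(20):
            nv = ds.NutrientVector(
                energy=float(rng.uniform(500, 3500)),
                sodium=float(rng.uniform(500, 6000)),
            )
            gv = ds.FoodGroupVector.from_array(
                rng.uniform(0, 3, len(ds.GROUP_FIELDS))
            )
            res = ds.hei_score(nv, gv)
            assert res.total == pytest.approx(sum(res.components.values()))
            assert 0.0 <= res.total <= 100.0

    def test_energy_rescaling_invariance(self, rng):
        """Multiplying all amounts and energy by a constant leaves every
        density component, hence the total, unchanged."""
        nv = ds.NutrientVector(energy=1800.0, sodium=3000.0)
        gv = ds.FoodGroupVector(
            total_fruit=0.9, whole_fruit=0.3, total_veg=1.5, greens_beans=0.1,
            whole_grains=1.0, refined_grains=4.0, dairy=1.2, total_protein=5.0,
            seafood_plant_protein=0.5, mufa=20.0, pufa=10.0, sfa=15.0,
            added_sugar=12.0, solid_fat_kcal=300.0, alcohol=8.0,
        )
        base = ds.hei_score(nv, gv).total
        for c in (0.25, 2.0, 7.3):
            scaled = ds.hei_score(c * nv, c * gv).total
            assert scaled == pytest.approx(base, rel=1e-9)


class TestVectorisedScoring:
    def test_frame_scoring_matches_scalar(self, small_population):
        _, days = small_population
        sr = ds.apply_scenario(days[:80], None, ds.SubstitutionPolicy())
        frame_scores = hei_scores_frame(sr.modified)
        for i in range(0, 80, 7):
            nv = ds.NutrientVector.from_array(
                sr.modified.iloc[i][list(ds.NUTRIENT_FIELDS)].to_numpy(float)
            )
            gv = ds.FoodGroupVector.from_array(
                sr.modified.iloc[i][["fg_" + f for f in ds.GROUP_FIELDS]].to_numpy(float)
            )
            assert frame_scores["total"].iloc[i] == pytest.approx(
                ds.hei_score(nv, gv).total, rel=1e-9
            )

    def test_frame_scoring_zero_energy_row(self):
        cols = {f: [0.0] for f in ds.NUTRIENT_FIELDS}
        cols.update({"fg_" + f: [2.0] for f in ds.GROUP_FIELDS})
        assert hei_scores_frame(pd.DataFrame(cols))["total"].iloc[0] == 0.0
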