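"""Synthetic NHANES-like recall populations with known ground truth.

The generator emulates the structure the estimation pipeline needs —
stratified two-PSU-per-stratum sampling with unequal lognormal weights,
person-days built from background food items plus a Poisson number of
"typical sandwich" items — while keeping every population parameter
known, so analytic expectations (e.g. the mean intake shift under a
sandwich substitution) can be checked end to end.

Default conditions: the per-person-day sandwich rate is 0.78 and the
background per-nutrient means are chosen so that the scenario-0
population mean daily intake matches typical US-adult daily intakes
(energy ≈ 2302 kcal, sodium ≈ 3862 mg, ...). Background items are
truncated-normal; sandwich items are the configured profile with
mean-one multiplicative lognormal noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .composite import FoodDB
from .datamodel import (
    GROUP_FIELDS,
    NUTRIENT_FIELDS,
    FoodGroupVector,
    FoodItem,
    NutrientVector,
    PersonDay,
    SandwichProfile,
    ValidationError,
)
from .io import load_builtin_profiles

__all__ = [
    "PopulationConfig",
    "BASELINE_DAILY_MEANS",
    "default_background_means",
    "gen_food_db",
    "gen_population",
    "expected_scenario_shift",
    "SANDWICH_CATEGORY",
]

#: WWEIA category stamped on generated sandwich items (a cold-cut
#: sandwich category present in the default substitution policy).
SANDWICH_CATEGORY = 3202

#: Typical US-adult mean daily intakes under the current (scenario-0)
#: dietary pattern; used to anchor the synthetic background diet.
BASELINE_DAILY_MEANS: dict[str, float] = {
    "energy": 2302.0,
    "carbohydrate": 250.0,
    "protein": 80.0,
    "total_fat": 89.2,
    "saturated_fat": 29.5,
    "dietary_fiber": 16.2,
    "iron": 16.1,
    "calcium": 1030.0,
    "magnesium": 303.0,
    "potassium": 2779.0,
    "sodium": 3862.0,
    "folate_dfe": 556.1,
    "niacin": 27.7,
    "riboflavin": 2.32,
    "thiamin": 1.76,
    "vitamin_a_rae": 596.0,
    "vitamin_c": 81.2,
    "vitamin_d": 4.7,
    "vitamin_e_at": 8.0,
    "added_sugar": 20.3,
}

#: Background (non-sandwich) daily food-group equivalents for a typical
#: US-adult day; tuned to yield a plausible mid-range HEI-2010 score.
BACKGROUND_GROUP_MEANS: dict[str, float] = {
    "total_fruit": 1.0,
    "whole_fruit": 0.5,
    "total_veg": 1.4,
    "greens_beans": 0.15,
    "whole_grains": 0.85,
    "refined_grains": 5.5,
    "dairy": 1.5,
    "total_protein": 6.0,
    "seafood_plant_protein": 0.4,
    "mufa": 24.0,
    "pufa": 17.0,
    "sfa": 22.0,
    "added_sugar": 20.3,
    "solid_fat_kcal": 380.0,
    "alcohol": 10.0,
}


def default_background_means(
    sandwich_profile: SandwichProfile, sandwich_rate: float
) -> NutrientVector:
    """Background per-day nutrient means so that background + rate × profile
    reproduces :data:`BASELINE_DAILY_MEANS` in expectation."""
    base = np.array([BASELINE_DAILY_MEANS[f] for f in NUTRIENT_FIELDS])
    bg = base - sandwich_rate * sandwich_profile.nutrients.as_array()
    return NutrientVector.from_array(np.clip(bg, 0.0, None))


def _default_profile() -> SandwichProfile:
    return load_builtin_profiles()["Sandwich 0"]


@dataclass(frozen=True)
class PopulationConfig:
    """Ground-truth parameters of a synthetic recall population."""

    n_participants: int = 2000
    n_strata: int = 14
    psus_per_stratum: int = 2
    weight_meanlog: float = 0.0
    weight_sdlog: float = 0.5
    mean_items: float = 8.0
    sandwich_rate: float = 0.78
    sandwich_profile: SandwichProfile = field(default_factory=_default_profile)
    background_mean: NutrientVector | None = None
    background_cv: float = 0.25
    background_groups_mean: FoodGroupVector = field(
        default_factory=lambda: FoodGroupVector(**BACKGROUND_GROUP_MEANS)
    )
    profile_noise_cv: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 4:
            raise ValidationError("need n_participants >= 4")
        if self.psus_per_stratum < 2:
            raise ValidationError("need >= 2 PSUs per stratum")
        if self.sandwich_rate < 0 or self.background_cv < 0 or self.profile_noise_cv < 0:
            raise ValidationError("rates and CVs must be >= 0")

    def resolved_background_mean(self) -> NutrientVector:
        if self.background_mean is not None:
            return self.background_mean
        return default_background_means(self.sandwich_profile, self.sandwich_rate)

    def with_seed(self, seed: int) -> "PopulationConfig":
        return replace(self, seed=seed)


def gen_food_db(seed: int, n_foods: int) -> FoodDB:
    """A reproducible toy food database with at least one food per
    HEI-relevant group (per-100 g densities)."""
    if n_foods < 1:
        raise ValidationError("n_foods >= 1 required")
    rng = np.random.default_rng(seed)
    primary_groups = [
        "whole_grains", "refined_grains", "dairy", "total_protein",
        "total_fruit", "total_veg", "greens_beans", "whole_fruit",
        "seafood_plant_protein",
    ]
    rows = []
    for i in range(n_foods):
        code = 10_000_001 + i
        nutrients = {
            f: round(float(rng.uniform(0, hi)), 4)
            for f, hi in zip(
                NUTRIENT_FIELDS,
                [400, 60, 30, 25, 10, 6, 5, 300, 80, 500, 900, 150, 8, 1, 1, 150, 40, 2, 3, 4],
            )
        }
        groups = {("fg_" + f): 0.0 for f in GROUP_FIELDS}
        g = primary_groups[i % len(primary_groups)]
        groups["fg_" + g] = round(float(rng.uniform(0.5, 4.0)), 4)
        # containment invariants of the group vector
        if g == "whole_fruit":
            groups["fg_total_fruit"] = groups["fg_whole_fruit"]
        if g == "greens_beans":
            groups["fg_total_veg"] = groups["fg_greens_beans"]
        if g == "seafood_plant_protein":
            groups["fg_total_protein"] = groups["fg_seafood_plant_protein"]
        groups["fg_sfa"] = nutrients["saturated_fat"]
        rows.append({"food_code": code, **nutrients, **groups})
    return FoodDB(pd.DataFrame(rows).set_index("food_code"))


def _truncnorm(rng: np.random.Generator, mean: np.ndarray, cv: float) -> np.ndarray:
    draw = rng.normal(mean, cv * mean)
    return np.clip(draw, 0.0, None)


def gen_population(config: PopulationConfig) -> list[PersonDay]:
    """Generate person-days with known sandwich content and design labels.

    Strata and PSUs are assigned round-robin so every stratum carries the
    configured number of PSUs; weights are lognormal; each day holds a
    Poisson number of background items plus Poisson(sandwich_rate)
    sandwich items stamped with :data:`SANDWICH_CATEGORY`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    bg_mean = config.resolved_background_mean().as_array()
    bg_groups = config.background_groups_mean.as_array()
    prof_nv = config.sandwich_profile.nutrients.as_array()
    prof_gv = config.sandwich_profile.groups.as_array()
    sigma = np.sqrt(np.log1p(config.profile_noise_cv**2))

    days: list[PersonDay] = []
    for i in range(config.n_participants):
        stratum = f"S{i % config.n_strata + 1:02d}"
        psu = f"P{(i // config.n_strata) % config.psus_per_stratum + 1}"
        weight = float(
            rng.lognormal(config.weight_meanlog, config.weight_sdlog)
        )
        day = PersonDay(
            participant_id=f"ID{i + 1:06d}", stratum=stratum, psu=psu, weight=weight
        )
        n_bg = int(rng.poisson(config.mean_items))
        for j in range(n_bg):
            nv = _truncnorm(rng, bg_mean / config.mean_items, config.background_cv)
            gv = _truncnorm(rng, bg_groups / config.mean_items, config.background_cv)
            day.items.append(
                FoodItem(
                    food_code=20_000_000 + j,
                    wweia_category=1000,
                    amount=float(rng.uniform(20, 400)),
                    nutrients=NutrientVector.from_array(nv),
                    groups=_repair_groups(gv),
                )
            )
        n_sw = int(rng.poisson(config.sandwich_rate))
        for j in range(n_sw):
            # mean-one lognormal factor applied to the whole profile
            factor = float(rng.lognormal(-0.5 * sigma**2, sigma)) if sigma > 0 else 1.0
            day.items.append(
                FoodItem(
                    food_code=58_100_000 + j,
                    wweia_category=SANDWICH_CATEGORY,
                    amount=float(rng.uniform(150, 350)),
                    nutrients=NutrientVector.from_array(prof_nv * factor),
                    groups=FoodGroupVector.from_array(prof_gv * factor),
                )
            )
        day.validate()
        days.append(day)
    return days


def _repair_groups(arr: np.ndarray) -> FoodGroupVector:
    """Enforce the containment invariants after independent noise."""
    gv = dict(zip(GROUP_FIELDS, arr.tolist()))
    gv["whole_fruit"] = min(gv["whole_fruit"], gv["total_fruit"])
    gv["greens_beans"] = min(gv["greens_beans"], gv["total_veg"])
    gv["seafood_plant_protein"] = min(gv["seafood_plant_protein"], gv["total_protein"])
    return FoodGroupVector(**gv)


def expected_scenario_shift(
    config: PopulationConfig,
    profile_in: SandwichProfile,
    profile_out: SandwichProfile,
) -> NutrientVector:
    """Analytic expected change in population mean daily intake when
    every occurrence of ``profile_in`` is replaced by ``profile_out``:
    sandwich_rate × (profile_out − profile_in)."""
    delta = profile_out.nutrients.as_array() - profile_in.nutrients.as_array()
    return NutrientVector.from_array(config.sandwich_rate * delta)
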