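"""Healthy Eating Index 2010 component and total scoring.

HEI-2010 scores a day's diet 0–100 across 12 components. Eight adequacy
components (fruit, vegetables, whole grains, dairy, protein foods) and
three moderation components (refined grains, sodium, empty calories) are
scored on densities per 1,000 kcal; the fatty-acid component scores the
(MUFA+PUFA)/SFA ratio. Every component interpolates linearly between its
zero-score and max-score standard and is clipped to [0, max points].

Scoring here is person-level: each person-day is scored on its own
totals and the population score is the survey-weighted mean of the
per-day totals (the population-ratio method — densities of summed
population intakes — is deliberately not implemented).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .datamodel import FoodGroupVector, NutrientVector

__all__ = [
    "ComponentStandard",
    "HEIResult",
    "STANDARDS",
    "densities",
    "component_score",
    "hei_score",
    "hei_scores_frame",
]

ALCOHOL_KCAL_PER_G = 7.0
ADDED_SUGAR_KCAL_PER_TSP = 16.0
ALCOHOL_THRESHOLD_G_PER_1000 = 13.0


@dataclass(frozen=True)
class ComponentStandard:
    """Piecewise-linear scoring standard for one HEI-2010 component."""

    name: str
    max_points: float
    basis: str           # density | ratio | percent_energy
    value_at_zero: float
    value_at_max: float
    direction: str       # adequacy | moderation

    def __post_init__(self) -> None:
        if self.value_at_max == self.value_at_zero:
            raise ValueError(f"{self.name}: degenerate standard")
        if self.direction == "adequacy" and not self.value_at_max > self.value_at_zero:
            raise ValueError(f"{self.name}: adequacy requires value_at_max > value_at_zero")
        if self.direction == "moderation" and not self.value_at_max < self.value_at_zero:
            raise ValueError(f"{self.name}: moderation requires value_at_max < value_at_zero")


def _load_standards() -> dict[str, ComponentStandard]:
    with resources.files("dietshift.data").joinpath("hei2010_standards.csv").open() as fh:
        df = pd.read_csv(fh)
    return {
        r["name"]: ComponentStandard(
            name=r["name"],
            max_points=float(r["max_points"]),
            basis=r["basis"],
            value_at_zero=float(r["value_at_zero"]),
            value_at_max=float(r["value_at_max"]),
            direction=r["direction"],
        )
        for _, r in df.iterrows()
    }


#: The 12 fixed HEI-2010 standards, loaded from the packaged CSV resource.
STANDARDS: dict[str, ComponentStandard] = _load_standards()

COMPONENT_NAMES: tuple[str, ...] = tuple(STANDARDS)


@dataclass(frozen=True)
class HEIResult:
    """Twelve component scores and their 0–100 total."""

    components: dict[str, float]
    total: float


def densities(
    nutrients: NutrientVector, groups: FoodGroupVector
) -> dict[str, float]:
    """Component input values: amounts per 1,000 kcal, the fatty-acid
    ratio, and the empty-calorie percentage of energy.

    With zero energy every value is NaN (undefined; scored 0 downstream).
    A zero-SFA day with MUFA+PUFA > 0 gets an infinite ratio (max points).
    """
    e = nutrients.energy
    if e <= 0:
        return {name: math.nan for name in COMPONENT_NAMES}
    per1000 = 1000.0 / e
    unsat = groups.mufa + groups.pufa
    if groups.sfa > 0:
        ratio = unsat / groups.sfa
    else:
        ratio = math.inf if unsat > 0 else 0.0
    alcohol_per_1000 = groups.alcohol * per1000
    excess_alcohol_g = max(0.0, alcohol_per_1000 - ALCOHOL_THRESHOLD_G_PER_1000) * e / 1000.0
    empty_kcal = (
        groups.solid_fat_kcal
        + ADDED_SUGAR_KCAL_PER_TSP * groups.added_sugar
        + ALCOHOL_KCAL_PER_G * excess_alcohol_g
    )
    return {
        "total_fruit": groups.total_fruit * per1000,
        "whole_fruit": groups.whole_fruit * per1000,
        "total_veg": groups.total_veg * per1000,
        "greens_beans": groups.greens_beans * per1000,
        "whole_grains": groups.whole_grains * per1000,
        "dairy": groups.dairy * per1000,
        "total_protein": groups.total_protein * per1000,
        "seafood_plant_protein": groups.seafood_plant_protein * per1000,
        "fatty_acids": ratio,
        "refined_grains": groups.refined_grains * per1000,
        "sodium": nutrients.sodium / 1000.0 * per1000,  # g per 1,000 kcal
        "empty_calories": empty_kcal * 100.0 / e,
    }


def component_score(value: float, standard: ComponentStandard) -> float:
    """Linear interpolation between the zero- and max-score standards,
    clipped to [0, max_points]; undefined (NaN) values score 0."""
    if math.isnan(value):
        return 0.0
    if math.isinf(value):
        return standard.max_points if standard.direction == "adequacy" else 0.0
    frac = (value - standard.value_at_zero) / (standard.value_at_max - standard.value_at_zero)
    return float(np.clip(frac, 0.0, 1.0) * standard.max_points)


def hei_score(nutrients: NutrientVector, groups: FoodGroupVector) -> HEIResult:
    """Score one day's totals; a zero-energy day scores 0 on everything."""
    vals = densities(nutrients, groups)
    comps = {name: component_score(vals[name], STANDARDS[name]) for name in COMPONENT_NAMES}
    return HEIResult(components=comps, total=float(sum(comps.values())))


def hei_scores_frame(totals: pd.DataFrame) -> pd.DataFrame:
    """Vectorised HEI-2010 over a totals DataFrame (one row per person-day,
    nutrient columns plain, food-group columns prefixed ``fg_``).

    Returns a DataFrame with one column per component plus ``total``.
    """
    e = totals["energy"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        per1000 = np.where(e > 0, 1000.0 / e, np.nan)
    unsat = totals["fg_mufa"].to_numpy(float) + totals["fg_pufa"].to_numpy(float)
    sfa = totals["fg_sfa"].to_numpy(float)
    ratio = np.full_like(e, np.nan)
    pos = sfa > 0
    ratio[pos] = unsat[pos] / sfa[pos]
    ratio[~pos & (unsat > 0)] = np.inf
    ratio[~pos & (unsat <= 0)] = 0.0
    ratio[~(e > 0)] = np.nan

    alcohol_per_1000 = totals["fg_alcohol"].to_numpy(float) * per1000
    excess_g = np.maximum(0.0, alcohol_per_1000 - ALCOHOL_THRESHOLD_G_PER_1000) * e / 1000.0
    empty_kcal = (
        totals["fg_solid_fat_kcal"].to_numpy(float)
        + ADDED_SUGAR_KCAL_PER_TSP * totals["fg_added_sugar"].to_numpy(float)
        + ALCOHOL_KCAL_PER_G * excess_g
    )
    values = {
        "total_fruit": totals["fg_total_fruit"].to_numpy(float) * per1000,
        "whole_fruit": totals["fg_whole_fruit"].to_numpy(float) * per1000,
        "total_veg": totals["fg_total_veg"].to_numpy(float) * per1000,
        "greens_beans": totals["fg_greens_beans"].to_numpy(float) * per1000,
        "whole_grains": totals["fg_whole_grains"].to_numpy(float) * per1000,
        "dairy": totals["fg_dairy"].to_numpy(float) * per1000,
        "total_protein": totals["fg_total_protein"].to_numpy(float) * per1000,
        "seafood_plant_protein": totals["fg_seafood_plant_protein"].to_numpy(float) * per1000,
        "fatty_acids": ratio,
        "refined_grains": totals["fg_refined_grains"].to_numpy(float) * per1000,
        "sodium": totals["sodium"].to_numpy(float) / 1000.0 * per1000,
        "empty_calories": np.where(e > 0, empty_kcal * 100.0 / e, np.nan),
    }
    out = {}
    for name, v in values.items():
        std = STANDARDS[name]
        span = std.value_at_max - std.value_at_zero
        frac = (v - std.value_at_zero) / span
        score = np.clip(frac, 0.0, 1.0) * std.max_points
        score = np.where(np.isnan(v), 0.0, score)
        if std.direction == "adequacy":
            score = np.where(np.isposinf(v), std.max_points, score)
        out[name] = score
    df = pd.DataFrame(out, index=totals.index)
    df["total"] = df.sum(axis=1)
    return df
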