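"""Replace typical-sandwich items with a modeled composite, at the
daily-totals level.

Each item whose WWEIA category or food code matches the policy is treated
as one sandwich occurrence; its nutrient and food-group contribution is
removed from the day's totals and one fixed-size modeled sandwich is
injected in its place. Replacement is per occurrence and never scaled by
the replaced item's grams: the composites are prespecified amounts, not
per-gram recipes. Item lists are left untouched — downstream analysis
consumes daily totals only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import (
    GROUP_FIELDS,
    NUTRIENT_FIELDS,
    FoodGroupVector,
    NutrientVector,
    PersonDay,
    SandwichProfile,
    ValidationError,
)

logger = logging.getLogger("dietshift")

__all__ = [
    "DEFAULT_SANDWICH_CATEGORIES",
    "SubstitutionPolicy",
    "ScenarioResult",
    "daily_totals",
    "identify_sandwiches",
    "substitute_day",
    "apply_scenario",
]

# WWEIA main-category codes for burgers, frankfurters/sausages and
# cold-cut / poultry / egg-and-other sandwiches. An editable default,
# not a claim of fidelity to any particular analysis run.
DEFAULT_SANDWICH_CATEGORIES: frozenset[int] = frozenset(
    {3002, 3004, 3006, 3202, 3204, 3206, 3208}
)


@dataclass(frozen=True)
class SubstitutionPolicy:
    """Which items count as typical sandwiches.

    An item is flagged when its WWEIA category is in
    ``sandwich_categories`` or its 8-digit food code is in
    ``sandwich_food_codes``. Granularity is per item occurrence with no
    portion scaling.
    """

    sandwich_categories: frozenset[int] = DEFAULT_SANDWICH_CATEGORIES
    sandwich_food_codes: frozenset[int] = frozenset()

    def validate(self) -> None:
        if not self.sandwich_categories and not self.sandwich_food_codes:
            raise ValidationError("substitution policy matches nothing")


@dataclass
class ScenarioResult:
    """Per-participant baseline and scenario-modified daily totals.

    ``baseline`` and ``modified`` are aligned DataFrames with one row per
    person-day and one column per nutrient/food-group field;
    ``n_replaced`` counts sandwich occurrences replaced per person-day.
    """

    participant_ids: list[str]
    strata: list[str]
    psus: list[str]
    weights: np.ndarray
    baseline: pd.DataFrame
    modified: pd.DataFrame
    n_replaced: np.ndarray
    profile_name: str = ""

    COLUMNS = list(NUTRIENT_FIELDS) + ["fg_" + f for f in GROUP_FIELDS]

    def design_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": self.participant_ids,
                "stratum": self.strata,
                "psu": self.psus,
                "weight": self.weights,
            }
        )


def daily_totals(day: PersonDay) -> tuple[NutrientVector, FoodGroupVector]:
    """Component-wise sum of the day's items (zero vectors for an empty day)."""
    nv = NutrientVector.zeros()
    gv = FoodGroupVector.zeros()
    for item in day.items:
        nv = nv + item.nutrients
        gv = gv + item.groups
    return nv, gv


def identify_sandwiches(day: PersonDay, policy: SubstitutionPolicy) -> list[int]:
    """Indices (in item order) of items the policy treats as typical sandwiches."""
    return [
        i
        for i, item in enumerate(day.items)
        if item.wweia_category in policy.sandwich_categories
        or item.food_code in policy.sandwich_food_codes
    ]


def substitute_day(
    day: PersonDay,
    profile: SandwichProfile | None,
    policy: SubstitutionPolicy,
) -> tuple[NutrientVector, FoodGroupVector, NutrientVector, FoodGroupVector, int]:
    """Substitute each flagged sandwich occurrence with ``profile``.

    Returns ``(baseline_nutrients, baseline_groups, modified_nutrients,
    modified_groups, n_replaced)``. ``profile=None`` is the pass-through
    baseline scenario. Negative modified totals (possible only with
    inconsistent inputs) are clamped to zero with a warning.
    """
    base_nv, base_gv = daily_totals(day)
    if profile is None:
        return base_nv, base_gv, base_nv, base_gv, 0
    idx = identify_sandwiches(day, policy)
    mod_nv, mod_gv = base_nv, base_gv
    for i in idx:
        mod_nv = mod_nv - day.items[i].nutrients + profile.nutrients
        mod_gv = mod_gv - day.items[i].groups + profile.groups
    nv_arr, gv_arr = mod_nv.as_array(), mod_gv.as_array()
    if (nv_arr < 0).any() or (gv_arr < 0).any():
        logger.warning(
            "participant %s: negative modified total clamped to 0",
            day.participant_id,
        )
        mod_nv = NutrientVector.from_array(np.clip(nv_arr, 0, None))
        mod_gv = FoodGroupVector.from_array(np.clip(gv_arr, 0, None))
    return base_nv, base_gv, mod_nv, mod_gv, len(idx)


def apply_scenario(
    dataset: list[PersonDay],
    profile: SandwichProfile | None,
    policy: SubstitutionPolicy,
    name: str | None = None,
) -> ScenarioResult:
    """Apply :func:`substitute_day` independently to every person-day.

    ``profile=None`` gives the baseline scenario: modified totals equal
    the baseline and no occurrences are replaced.
    """
    if not dataset:
        raise ValidationError("apply_scenario: empty dataset")
    rows_base, rows_mod, counts = [], [], []
    for day in dataset:
        b_nv, b_gv, m_nv, m_gv, k = substitute_day(day, profile, policy)
        rows_base.append(np.concatenate([b_nv.as_array(), b_gv.as_array()]))
        rows_mod.append(np.concatenate([m_nv.as_array(), m_gv.as_array()]))
        counts.append(k)
    cols = ScenarioResult.COLUMNS
    return ScenarioResult(
        participant_ids=[d.participant_id for d in dataset],
        strata=[d.stratum for d in dataset],
        psus=[d.psu for d in dataset],
        weights=np.array([d.weight for d in dataset], dtype=float),
        baseline=pd.DataFrame(rows_base, columns=cols),
        modified=pd.DataFrame(rows_mod, columns=cols),
        n_replaced=np.array(counts, dtype=int),
        profile_name="baseline" if profile is None else profile.name,
    )
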