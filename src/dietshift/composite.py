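"""Build sandwich composites by proportional-consumption weighting.

A composite is defined by prespecified food-group targets (e.g. 2 oz eq
of whole grains, 1 cup eq of dairy). Within each targeted group, the
qualifying food codes are weighted by how much of them the surveyed
population actually eats — survey weight × grams summed over person-days
— and each food contributes its weight's share of the group target. The
grams of a food needed to supply ``target × weight`` equivalents follow
from its equivalent density (equivalents per gram), and the composite's
nutrients are the gram-weighted sum of the foods' nutrient densities.
By construction the composite's food-group vector equals the targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .datamodel import (
    GROUP_FIELDS,
    NUTRIENT_FIELDS,
    FoodGroupVector,
    NutrientVector,
    PersonDay,
    SandwichProfile,
    ValidationError,
)

__all__ = ["CompositeSpec", "FoodDB", "consumption_weights", "build_composite"]


@dataclass(frozen=True)
class CompositeSpec:
    """Food-group targets and the qualifying food codes for each group."""

    name: str
    targets: dict[str, float]                # group -> amount (oz/cup eq)
    qualifying_codes: dict[str, frozenset[int]]  # group -> food codes

    def validate(self) -> None:
        for g, t in self.targets.items():
            if g not in GROUP_FIELDS:
                raise ValidationError(f"unknown food group {g!r}")
            if not t > 0:
                raise ValidationError(f"target for {g} must be > 0, got {t}")
            if not self.qualifying_codes.get(g):
                raise ValidationError(f"no qualifying codes for targeted group {g}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CompositeSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        spec = cls(
            name=raw["name"],
            targets={k: float(v) for k, v in raw["targets"].items()},
            qualifying_codes={
                k: frozenset(int(c) for c in v)
                for k, v in raw["qualifying_codes"].items()
            },
        )
        spec.validate()
        return spec


@dataclass
class FoodDB:
    """Per-food-code nutrient and food-group densities, stored per 100 g."""

    table: pd.DataFrame = field(repr=False)  # index: food_code

    COLUMNS = list(NUTRIENT_FIELDS) + ["fg_" + f for f in GROUP_FIELDS]

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"FoodDB missing columns: {missing}")
        if self.table.index.has_duplicates:
            raise ValidationError("FoodDB: duplicate food codes")
        if (self.table[self.COLUMNS] < 0).any().any():
            raise ValidationError("FoodDB: negative density")

    @classmethod
    def from_csv(cls, path: str | Path) -> "FoodDB":
        return cls(pd.read_csv(path).set_index("food_code"))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index_label="food_code")

    def codes(self) -> list[int]:
        return [int(c) for c in self.table.index]

    def nutrients_per_gram(self, code: int) -> NutrientVector:
        row = self.table.loc[code]
        return NutrientVector(**{f: float(row[f]) / 100.0 for f in NUTRIENT_FIELDS})

    def group_density(self, code: int, group: str) -> float:
        """Equivalents of ``group`` per gram of the food."""
        return float(self.table.loc[code, "fg_" + group]) / 100.0


def consumption_weights(
    dataset: list[PersonDay], codes: set[int] | frozenset[int]
) -> dict[int, float]:
    """Population-consumption weights for a set of qualifying food codes.

    weight(f) = Σ_days survey_weight × grams of f, normalised over the
    code set. Codes never consumed get weight 0.
    """
    if not dataset:
        raise ValidationError("consumption_weights: empty dataset")
    mass = {int(c): 0.0 for c in codes}
    for day in dataset:
        for item in day.items:
            if item.food_code in mass:
                mass[item.food_code] += day.weight * item.amount
    total = sum(mass.values())
    if total <= 0:
        raise ValidationError("no consumption mass for any qualifying code")
    return {c: m / total for c, m in mass.items()}


def build_composite(
    spec: CompositeSpec, db: FoodDB, weights: dict[str, dict[int, float]]
) -> SandwichProfile:
    """Assemble a :class:`SandwichProfile` from group targets and weights.

    ``weights`` maps each targeted group to its per-code consumption
    weights (normalised within the group). For group ``g`` with target
    ``T`` a qualifying food ``f`` contributes ``T·w_f`` equivalents,
    requiring ``T·w_f / density_g(f)`` grams; composite nutrients are the
    gram-weighted sum.
    """
    spec.validate()
    nutrients = NutrientVector.zeros()
    group_amounts = dict.fromkeys(GROUP_FIELDS, 0.0)
    for group, target in spec.targets.items():
        w = weights[group]
        total_w = sum(v for v in w.values() if v > 0)
        if abs(total_w - 1.0) > 1e-9:
            raise ValidationError(f"weights for group {group} not normalised")
        for code, wf in w.items():
            if wf <= 0:
                continue
            if code not in db.codes():
                raise ValidationError(f"food code {code} not in database")
            dens = db.group_density(code, group)
            if dens <= 0:
                raise ValidationError(
                    f"food {code} has zero {group} equivalent density; "
                    "cannot realize target through that food"
                )
            grams = target * wf / dens
            nutrients = nutrients + grams * db.nutrients_per_gram(code)
        group_amounts[group] = target
    profile = SandwichProfile(
        name=spec.name,
        nutrients=nutrients,
        groups=FoodGroupVector(**group_amounts),
        groups_known=True,
    )
    profile.validate()
    return profile
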