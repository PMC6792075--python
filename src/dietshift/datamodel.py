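"""Shared domain types for 24-hour recall dietary modeling.

The central objects are per-day (or per-item) nutrient amounts
(:class:`NutrientVector`), food-pattern equivalents plus the fatty-acid
fields needed for HEI-2010 scoring (:class:`FoodGroupVector`), individual
reported foods (:class:`FoodItem`), the person-day recall unit
(:class:`PersonDay`) and named sandwich composites
(:class:`SandwichProfile`).

Units follow USDA reporting conventions: energy in kcal, macronutrients
and fiber in g, minerals in mg, folate as mcg DFE, vitamin A as mcg RAE,
vitamins C/E in mg, vitamin D in mcg, added sugar in teaspoon
equivalents; food groups in cup or ounce equivalents.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterator

import numpy as np

__all__ = [
    "NUTRIENT_FIELDS",
    "GROUP_FIELDS",
    "NutrientVector",
    "FoodGroupVector",
    "FoodItem",
    "PersonDay",
    "SandwichProfile",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when a domain invariant is violated."""


NUTRIENT_FIELDS: tuple[str, ...] = (
    "energy",          # kcal
    "carbohydrate",    # g
    "protein",         # g
    "total_fat",       # g
    "saturated_fat",   # g
    "dietary_fiber",   # g
    "iron",            # mg
    "calcium",         # mg
    "magnesium",       # mg
    "potassium",       # mg
    "sodium",          # mg
    "folate_dfe",      # mcg DFE
    "niacin",          # mg
    "riboflavin",      # mg
    "thiamin",         # mg
    "vitamin_a_rae",   # mcg RAE
    "vitamin_c",       # mg
    "vitamin_d",       # mcg
    "vitamin_e_at",    # mg alpha-tocopherol
    "added_sugar",     # tsp eq
)

GROUP_FIELDS: tuple[str, ...] = (
    "total_fruit",            # cup eq
    "whole_fruit",            # cup eq
    "total_veg",              # cup eq
    "greens_beans",           # cup eq
    "whole_grains",           # oz eq
    "refined_grains",         # oz eq
    "dairy",                  # cup eq
    "total_protein",          # oz eq
    "seafood_plant_protein",  # oz eq
    "mufa",                   # g
    "pufa",                   # g
    "sfa",                    # g
    "added_sugar",            # tsp eq
    "solid_fat_kcal",         # kcal
    "alcohol",                # g
)


class _VectorMixin:
    """Array conversion and element-wise arithmetic shared by the two vectors."""

    _FIELDS: tuple[str, ...] = ()

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self._FIELDS], dtype=float)

    @classmethod
    def from_array(cls, arr):
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(cls._FIELDS),):
            raise ValueError(f"expected {len(cls._FIELDS)} values, got {arr.shape}")
        return cls(**dict(zip(cls._FIELDS, arr.tolist())))

    @classmethod
    def zeros(cls):
        return cls.from_array(np.zeros(len(cls._FIELDS)))

    def __add__(self, other):
        return type(self).from_array(self.as_array() + other.as_array())

    def __sub__(self, other):
        return type(self).from_array(self.as_array() - other.as_array())

    def __mul__(self, c: float):
        return type(self).from_array(self.as_array() * float(c))

    __rmul__ = __mul__

    def __iter__(self) -> Iterator[float]:
        return (getattr(self, f) for f in self._FIELDS)

    def validate(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ValidationError(f"{type(self).__name__}: non-finite entry")
        if np.any(arr < 0):
            bad = [f for f, v in zip(self._FIELDS, arr) if v < 0]
            raise ValidationError(f"{type(self).__name__}: negative field(s) {bad}")


@dataclass(frozen=True)
class NutrientVector(_VectorMixin):
    """Daily or per-item amounts of energy and 19 nutrients."""

    energy: float = 0.0
    carbohydrate: float = 0.0
    protein: float = 0.0
    total_fat: float = 0.0
    saturated_fat: float = 0.0
    dietary_fiber: float = 0.0
    iron: float = 0.0
    calcium: float = 0.0
    magnesium: float = 0.0
    potassium: float = 0.0
    sodium: float = 0.0
    folate_dfe: float = 0.0
    niacin: float = 0.0
    riboflavin: float = 0.0
    thiamin: float = 0.0
    vitamin_a_rae: float = 0.0
    vitamin_c: float = 0.0
    vitamin_d: float = 0.0
    vitamin_e_at: float = 0.0
    added_sugar: float = 0.0

    _FIELDS = NUTRIENT_FIELDS


@dataclass(frozen=True)
class FoodGroupVector(_VectorMixin):
    """Food-pattern equivalents plus the fatty-acid/empty-calorie inputs of HEI-2010."""

    total_fruit: float = 0.0
    whole_fruit: float = 0.0
    total_veg: float = 0.0
    greens_beans: float = 0.0
    whole_grains: float = 0.0
    refined_grains: float = 0.0
    dairy: float = 0.0
    total_protein: float = 0.0
    seafood_plant_protein: float = 0.0
    mufa: float = 0.0
    pufa: float = 0.0
    sfa: float = 0.0
    added_sugar: float = 0.0
    solid_fat_kcal: float = 0.0
    alcohol: float = 0.0

    _FIELDS = GROUP_FIELDS

    def validate(self) -> None:
        super().validate()
        eps = 1e-9
        if self.whole_fruit > self.total_fruit + eps:
            raise ValidationError("whole_fruit exceeds total_fruit")
        if self.greens_beans > self.total_veg + eps:
            raise ValidationError("greens_beans exceeds total_veg")
        if self.seafood_plant_protein > self.total_protein + eps:
            raise ValidationError("seafood_plant_protein exceeds total_protein")


@dataclass(frozen=True)
class FoodItem:
    """One reported food: an 8-digit food code, WWEIA category, grams, and content."""

    food_code: int
    wweia_category: int
    amount: float  # g
    nutrients: NutrientVector
    groups: FoodGroupVector = field(default_factory=FoodGroupVector)

    def validate(self) -> None:
        if self.amount < 0:
            raise ValidationError(f"food {self.food_code}: negative amount {self.amount}")
        self.nutrients.validate()
        self.groups.validate()


@dataclass
class PersonDay:
    """A participant's Day-1 recall: design labels, survey weight and the item list."""

    participant_id: str
    stratum: str
    psu: str
    weight: float
    items: list[FoodItem] = field(default_factory=list)

    def validate(self) -> None:
        if not (np.isfinite(self.weight) and self.weight > 0):
            raise ValidationError(
                f"participant {self.participant_id}: weight must be > 0, got {self.weight}"
            )
        if not str(self.stratum) or not str(self.psu):
            raise ValidationError(f"participant {self.participant_id}: empty stratum/psu")
        for item in self.items:
            item.validate()


@dataclass(frozen=True)
class SandwichProfile:
    """A named sandwich composite: its nutrient content and food-group equivalents.

    ``groups_known`` is False when the source composite documents nutrients
    only, so the group fields are zero placeholders rather than measured
    equivalents.
    """

    name: str
    nutrients: NutrientVector
    groups: FoodGroupVector
    groups_known: bool = True

    def validate(self) -> None:
        if not self.name:
            raise ValidationError("profile name must be non-empty")
        self.nutrients.validate()
        self.groups.validate()


def nutrient_columns() -> list[str]:
    """Canonical CSV column names for nutrient fields."""
    return list(NUTRIENT_FIELDS)


def group_columns() -> list[str]:
    """Canonical CSV column names for food-group fields (prefixed to avoid
    clashing with the added_sugar nutrient column)."""
    return ["fg_" + f for f in GROUP_FIELDS]


# silence dataclass complaining about _FIELDS being in class namespace
for _cls in (NutrientVector, FoodGroupVector):
    if "_FIELDS" in {f.name for f in fields(_cls)}:  # pragma: no cover
        raise RuntimeError("_FIELDS leaked into dataclass fields")
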