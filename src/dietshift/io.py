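"""Readers and writers for recall tables, sandwich profiles and result tables.

The canonical interchange format is CSV with one row per reported food
item. Required columns::

    participant_id, stratum, psu, weight, food_code, amount_g,
    <the 20 nutrient columns of datamodel.NUTRIENT_FIELDS>

Optional columns: ``wweia_category`` (defaults to 0), ``day`` (Day-1 rows
are kept by default) and the food-group columns ``fg_*`` (filled with 0,
with a warning, when absent — HEI scoring then sees no equivalents).

SAS transport (.XPT) files, the NHANES distribution format, are read
through :func:`pandas.read_sas`; column names are lower-cased on read so
the same schema applies.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import pandas as pd

from .datamodel import (
    GROUP_FIELDS,
    NUTRIENT_FIELDS,
    FoodGroupVector,
    FoodItem,
    NutrientVector,
    PersonDay,
    SandwichProfile,
    ValidationError,
    group_columns,
)

logger = logging.getLogger("dietshift")

__all__ = ["read_recall_table", "load_builtin_profiles", "write_results", "read_results"]

REQUIRED_COLUMNS = (
    ["participant_id", "stratum", "psu", "weight", "food_code", "amount_g"]
    + list(NUTRIENT_FIELDS)
)

RESULT_TABLE_COLUMNS = ["quantity", "scenario", "mean", "se", "lcl99", "ucl99"]


def _frame_to_persondays(df: pd.DataFrame) -> list[PersonDay]:
    fg_cols = group_columns()
    days: list[PersonDay] = []
    for pid, sub in df.groupby("participant_id", sort=False):
        first = sub.iloc[0]
        day = PersonDay(
            participant_id=str(pid),
            stratum=str(first["stratum"]),
            psu=str(first["psu"]),
            weight=float(first["weight"]),
        )
        for idx, row in sub.iterrows():
            if row["amount_g"] < 0:
                raise ValidationError(f"row {idx}: negative amount_g {row['amount_g']}")
            if row["weight"] <= 0:
                raise ValidationError(f"row {idx}: non-positive weight {row['weight']}")
            nv = NutrientVector(**{f: float(row[f]) for f in NUTRIENT_FIELDS})
            gv = FoodGroupVector(
                **{f: float(row[c]) for f, c in zip(GROUP_FIELDS, fg_cols)}
            )
            item = FoodItem(
                food_code=int(row["food_code"]),
                wweia_category=int(row.get("wweia_category", 0)),
                amount=float(row["amount_g"]),
                nutrients=nv,
                groups=gv,
            )
            item.validate()
            day.items.append(item)
        day.validate()
        days.append(day)
    return days


def read_recall_table(
    path: str | Path, format: str | None = None, day: int = 1
) -> list[PersonDay]:
    """Read a person-day recall table into :class:`PersonDay` objects.

    Parameters
    ----------
    path : str or Path
        CSV file in the canonical schema, or a SAS transport (.XPT) file.
    format : {"csv", "xpt"}, optional
        Inferred from the file suffix when omitted.
    day : int
        Recall day to keep when a ``day`` column is present (Day 1 by
        default; supplements are never part of the schema).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "xpt" if path.suffix.lower() == ".xpt" else "csv"
    if format == "csv":
        df = pd.read_csv(path)
    elif format == "xpt":
        df = pd.read_sas(path, format="xport")
        df.columns = [str(c).lower() for c in df.columns]
        for col in ("participant_id", "stratum", "psu"):
            if col in df.columns and df[col].dtype == object:
                df[col] = df[col].map(
                    lambda v: v.decode() if isinstance(v, bytes) else v
                )
    else:
        raise ValueError(f"unknown format {format!r}")

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required column(s): {missing}")

    if "day" in df.columns:
        df = df[df["day"] == day]

    if "wweia_category" not in df.columns:
        df = df.assign(wweia_category=0)

    absent_fg = [c for c in group_columns() if c not in df.columns]
    if absent_fg:
        logger.warning(
            "food-group columns absent, filled with 0: %s", ", ".join(absent_fg)
        )
        df = df.assign(**{c: 0.0 for c in absent_fg})

    return _frame_to_persondays(df)


def _profile_from_row(row: pd.Series) -> SandwichProfile:
    nv = NutrientVector(**{f: float(row[f]) for f in NUTRIENT_FIELDS})
    gv = FoodGroupVector(
        **{f: float(row["fg_" + f]) for f in GROUP_FIELDS}
    )
    prof = SandwichProfile(
        name=str(row["name"]),
        nutrients=nv,
        groups=gv,
        groups_known=bool(int(row["groups_known"])),
    )
    prof.validate()
    return prof


def load_builtin_profiles() -> dict[str, SandwichProfile]:
    """Load the six packaged sandwich composites.

    ``Sandwich 0`` is the typically consumed sandwich (its food-group
    equivalents are not documented by the source composite table, so
    ``groups_known`` is False); ``Sandwich 1``–``Sandwich 5`` are the
    modeled whole-grain, enriched-grain and soft-corn-tortilla builds.
    """
    with resources.files("dietshift.data").joinpath("sandwich_profiles.csv").open() as fh:
        df = pd.read_csv(fh)
    return {str(r["name"]): _profile_from_row(r) for _, r in df.iterrows()}


def read_profiles_csv(path: str | Path) -> dict[str, SandwichProfile]:
    """Read sandwich profiles from a CSV in the packaged-fixture schema."""
    df = pd.read_csv(path)
    return {str(r["name"]): _profile_from_row(r) for _, r in df.iterrows()}


def write_results(tables: dict[str, pd.DataFrame], path: str | Path) -> list[Path]:
    """Write each result table to ``<path>/<name>.csv`` at full precision."""
    path = Path(path)
    if not tables:
        logger.warning("write_results: empty table set, nothing written")
        return []
    path.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in tables.items():
        out = path / f"{name}.csv"
        table.to_csv(out, index=False)
        written.append(out)
    return written


def read_results(path: str | Path) -> dict[str, pd.DataFrame]:
    """Read back a directory of result tables written by :func:`write_results`."""
    path = Path(path)
    out = {}
    for p in sorted(path.glob("*.csv")):
        df = pd.read_csv(p)
        if "scenario" in df.columns:  # scenario labels are labels, not numbers
            df["scenario"] = df["scenario"].astype(str)
        out[p.stem] = df
    return out


def persondays_to_frame(days: list[PersonDay]) -> pd.DataFrame:
    """Flatten person-days to the canonical one-row-per-item schema."""
    fg_cols = group_columns()
    rows = []
    for day in days:
        for item in day.items:
            row = {
                "participant_id": day.participant_id,
                "stratum": day.stratum,
                "psu": day.psu,
                "weight": day.weight,
                "day": 1,
                "food_code": item.food_code,
                "wweia_category": item.wweia_category,
                "amount_g": item.amount,
            }
            row.update(dict(zip(NUTRIENT_FIELDS, item.nutrients.as_array())))
            row.update(dict(zip(fg_cols, item.groups.as_array())))
            rows.append(row)
    return pd.DataFrame(rows)


def write_recall_table(days: list[PersonDay], path: str | Path) -> Path:
    """Write person-days as a canonical-schema CSV; returns the path."""
    path = Path(path)
    persondays_to_frame(days).to_csv(path, index=False)
    return path
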