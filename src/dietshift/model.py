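"""Statsmodels-style front end: a substitution model fitted to recall data.

:class:`SandwichSubstitutionModel` bundles a person-day dataset, a set of
sandwich profiles, the scenario list and the substitution policy.
``fit()`` runs every scenario — pass-through baseline plus one run per
modeled sandwich — scores HEI-2010 on each person-day's (modified)
totals, and estimates survey-weighted population means with linearized
SEs and 99% confidence limits for all 20 nutrients and the HEI total.
The :class:`SubstitutionResults` object carries the estimate table, the
paper-shaped report tables, the pairwise CI-non-overlap (meaningfulness)
matrices and a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datamodel import NUTRIENT_FIELDS, PersonDay, SandwichProfile, ValidationError
from .hei2010 import hei_scores_frame
from .io import load_builtin_profiles, read_recall_table, write_results
from .report import format_table
from .substitution import ScenarioResult, SubstitutionPolicy, apply_scenario
from .survey import SurveyDesign, SurveyEstimate, meaningful_difference, survey_estimate

__all__ = [
    "TABLE_GROUPS",
    "SandwichSubstitutionModel",
    "SubstitutionResults",
    "RunConfig",
    "run_pipeline",
]

#: Report-table layout: which estimated quantities appear in which output
#: table (the groupings used for nutrients to limit, nutrients of public
#: health concern, shortfall nutrients, enrichment nutrients, and HEI).
TABLE_GROUPS: dict[str, list[str]] = {
    "nutrients_to_limit": ["energy", "total_fat", "saturated_fat", "added_sugar", "sodium"],
    "public_health_concern": ["dietary_fiber", "calcium", "vitamin_d", "potassium"],
    "shortfall_nutrients": [
        "folate_dfe", "iron", "magnesium", "vitamin_a_rae", "vitamin_e_at", "vitamin_c",
    ],
    "enrichment_nutrients": ["thiamin", "riboflavin", "niacin"],
    "hei": ["hei_total"],
}

QUANTITIES: tuple[str, ...] = tuple(NUTRIENT_FIELDS) + ("hei_total",)


class SandwichSubstitutionModel:
    """Sandwich-substitution analysis of a person-day recall dataset.

    Parameters
    ----------
    days : list of PersonDay
        The Day-1 recall data.
    profiles : dict, optional
        name → :class:`SandwichProfile`; defaults to the six packaged
        composites.
    scenarios : dict, optional
        scenario label → profile name (or None for the pass-through
        baseline). Defaults to ``{"0": None, "1": "Sandwich 1", ...,
        "5": "Sandwich 5"}``.
    policy : SubstitutionPolicy, optional
        Which WWEIA categories / food codes count as typical sandwiches.
    """

    def __init__(
        self,
        days: list[PersonDay],
        profiles: dict[str, SandwichProfile] | None = None,
        scenarios: dict[str, str | None] | None = None,
        policy: SubstitutionPolicy | None = None,
    ) -> None:
        if not days:
            raise ValidationError("empty dataset")
        self.days = days
        self.profiles = profiles if profiles is not None else load_builtin_profiles()
        if scenarios is None:
            scenarios = {"0": None}
            for k in range(1, 6):
                name = f"Sandwich {k}"
                if name in self.profiles:
                    scenarios[str(k)] = name
        for label, pname in scenarios.items():
            if pname is not None and pname not in self.profiles:
                raise ValidationError(
                    f"scenario {label!r} references unknown profile {pname!r}"
                )
        if not scenarios:
            raise ValidationError("at least one scenario required")
        self.scenarios = scenarios
        self.policy = policy if policy is not None else SubstitutionPolicy()
        self.policy.validate()
        self.design = SurveyDesign.from_arrays(
            [d.stratum for d in days],
            [d.psu for d in days],
            [d.weight for d in days],
        )

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "SandwichSubstitutionModel":
        return cls(read_recall_table(path), **kwargs)

    def fit(
        self, level: float = 0.99, collapse_single_psu: bool = False
    ) -> "SubstitutionResults":
        """Run all scenarios and estimate survey-weighted means."""
        rows = []
        scenario_results: dict[str, ScenarioResult] = {}
        for label, pname in self.scenarios.items():
            profile = None if pname is None else self.profiles[pname]
            sr = apply_scenario(self.days, profile, self.policy, name=pname)
            scenario_results[label] = sr
            totals = sr.modified
            hei = hei_scores_frame(totals)
            values = {q: totals[q].to_numpy(float) for q in NUTRIENT_FIELDS}
            values["hei_total"] = hei["total"].to_numpy(float)
            for q in QUANTITIES:
                est = survey_estimate(
                    values[q], self.design, level=level,
                    collapse_single_psu=collapse_single_psu,
                )
                rows.append(
                    {
                        "quantity": q,
                        "scenario": label,
                        "profile": pname if pname is not None else "baseline",
                        "mean": est.mean,
                        "se": est.se,
                        "lcl99": est.lcl,
                        "ucl99": est.ucl,
                        "df": est.df,
                        "n": len(self.days),
                    }
                )
        estimates = pd.DataFrame(rows)
        return SubstitutionResults(
            model=self,
            estimates=estimates,
            scenario_results=scenario_results,
            level=level,
        )


@dataclass
class SubstitutionResults:
    """Fitted scenario estimates with report tables and decision rules."""

    model: SandwichSubstitutionModel
    estimates: pd.DataFrame
    scenario_results: dict[str, ScenarioResult] = field(repr=False)
    level: float = 0.99

    def estimate(self, quantity: str, scenario: str) -> SurveyEstimate:
        row = self.estimates[
            (self.estimates["quantity"] == quantity)
            & (self.estimates["scenario"] == scenario)
        ]
        if len(row) != 1:
            raise KeyError((quantity, scenario))
        r = row.iloc[0]
        return SurveyEstimate(
            mean=r["mean"], se=r["se"], lcl=r["lcl99"], ucl=r["ucl99"],
            df=int(r["df"]), level=self.level,
        )

    def replacement_counts(self) -> dict[str, int]:
        return {
            label: int(sr.n_replaced.sum())
            for label, sr in self.scenario_results.items()
        }

    def tables(self) -> dict[str, pd.DataFrame]:
        """The five report tables (quantity, scenario, mean, se, lcl99, ucl99)."""
        cols = ["quantity", "scenario", "mean", "se", "lcl99", "ucl99"]
        out = {}
        for name, quantities in TABLE_GROUPS.items():
            sub = self.estimates[self.estimates["quantity"].isin(quantities)]
            sub = sub.sort_values(
                ["quantity", "scenario"],
                key=lambda s: s.map({q: i for i, q in enumerate(quantities)})
                if s.name == "quantity" else s,
            )
            out[name] = sub[cols].reset_index(drop=True)
        return out

    def meaningful_matrix(self, quantity: str) -> pd.DataFrame:
        """Pairwise CI-non-overlap flags between scenarios for one quantity."""
        labels = list(self.model.scenarios)
        ests = {s: self.estimate(quantity, s) for s in labels}
        mat = pd.DataFrame(False, index=labels, columns=labels)
        for a in labels:
            for b in labels:
                if a != b:
                    mat.loc[a, b] = meaningful_difference(ests[a], ests[b])
        return mat

    def meaningful_matrices(self) -> dict[str, pd.DataFrame]:
        return {q: self.meaningful_matrix(q) for q in QUANTITIES}

    def summary(self) -> str:
        """Text report: per-table Mean ± SE and 99% CLs per scenario."""
        parts = [
            f"Sandwich substitution analysis: n={len(self.model.days)} person-days, "
            f"{len(self.model.scenarios)} scenarios, level={self.level:.2f}",
            f"replacements per scenario: {self.replacement_counts()}",
        ]
        for name, table in self.tables().items():
            parts.append(f"\n== {name} ==")
            parts.append(format_table(table))
        return "\n".join(parts)

    def save(self, outdir: str | Path) -> list[Path]:
        """Write the five report tables plus the full estimate table as CSVs."""
        tables = dict(self.tables())
        tables["estimates_full"] = self.estimates
        return write_results(tables, outdir)


@dataclass
class RunConfig:
    """One-shot pipeline configuration (YAML-loadable).

    Either ``input_csv`` or ``synthetic`` (a PopulationConfig parameter
    mapping) must be given. ``scenarios`` maps scenario labels to profile
    names, with None/"baseline" reserved for the pass-through scenario.
    """

    input_csv: str | None = None
    synthetic: dict | None = None
    scenarios: dict[str, str | None] | None = None
    sandwich_categories: list[int] | None = None
    sandwich_food_codes: list[int] | None = None
    outdir: str = "results"
    level: float = 0.99
    collapse_single_psu: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if raw.get("scenarios"):
            cfg.scenarios = {
                str(k): (None if v in (None, "baseline") else str(v))
                for k, v in raw["scenarios"].items()
            }
        return cfg


def run_pipeline(config: RunConfig) -> SubstitutionResults:
    """Load or generate data, fit the model, and write the report tables."""
    policy_kwargs = {}
    if config.sandwich_categories is not None:
        policy_kwargs["sandwich_categories"] = frozenset(config.sandwich_categories)
    if config.sandwich_food_codes is not None:
        policy_kwargs["sandwich_food_codes"] = frozenset(config.sandwich_food_codes)
    policy = SubstitutionPolicy(**policy_kwargs) if policy_kwargs else None

    if config.input_csv is not None:
        days = read_recall_table(config.input_csv)
    elif config.synthetic is not None:
        from .synthetic import PopulationConfig, gen_population

        pc = PopulationConfig(**{**config.synthetic, "seed": config.seed})
        days = gen_population(pc)
    else:
        raise ValidationError("config needs input_csv or synthetic")

    model = SandwichSubstitutionModel(
        days, scenarios=config.scenarios, policy=policy
    )
    results = model.fit(
        level=config.level, collapse_single_psu=config.collapse_single_psu
    )
    results.save(config.outdir)
    return results
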