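"""Survey-weighted means with Taylor-linearized variance for stratified
cluster designs, and the 99% CI non-overlap decision rule.

The estimator is the weighted ratio mean ȳ = Σwy/Σw. Its variance is
estimated by linearization under with-replacement sampling of PSUs within
strata: with score values z = w·(y − ȳ) totalled to PSU level,

    var(ȳ) = [ Σ_h n_h/(n_h−1) Σ_i (z_hi − z̄_h)² ] / (Σw)²

with degrees of freedom (#PSUs − #strata) and a two-sided Student-t
quantile for the confidence limits — the convention of survey means
procedures. Two contrasts are deemed meaningful when their closed
confidence intervals do not overlap (a shared endpoint counts as
overlap).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import ValidationError

__all__ = [
    "SurveyDesign",
    "SurveyEstimate",
    "weighted_mean",
    "survey_estimate",
    "meaningful_difference",
]


@dataclass(frozen=True)
class SurveyDesign:
    """Per-observation stratum and PSU labels and sampling weights."""

    strata: np.ndarray
    psus: np.ndarray
    weights: np.ndarray

    @classmethod
    def from_arrays(cls, strata, psus, weights) -> "SurveyDesign":
        strata = np.asarray(strata)
        psus = np.asarray(psus)
        weights = np.asarray(weights, dtype=float)
        if not (len(strata) == len(psus) == len(weights)):
            raise ValidationError("design arrays must have equal length")
        if len(weights) == 0:
            raise ValidationError("empty design")
        if not np.all(weights > 0):
            raise ValidationError("weights must be > 0")
        return cls(strata=strata, psus=psus, weights=weights)

    def validate_for_variance(self, collapse_single_psu: bool = False) -> "SurveyDesign":
        """Check ≥2 PSUs per stratum; optionally collapse single-PSU strata
        into one synthetic stratum for robustness on real data."""
        strata = self.strata.astype(str)
        singles = [
            h for h in np.unique(strata)
            if len(np.unique(self.psus[strata == h])) < 2
        ]
        if not singles:
            return self
        if not collapse_single_psu:
            raise ValidationError(
                f"stratum/strata with a single PSU: {singles}; "
                "enable collapse_single_psu to pool them"
            )
        # qualify PSU labels by their original stratum so merging strata
        # never conflates distinct PSUs that happen to share a label
        psus = np.array(
            [f"{h}:{p}" for h, p in zip(strata, self.psus.astype(str))]
        )
        merged = np.where(np.isin(strata, singles), "__collapsed__", strata)
        pooled = merged == "__collapsed__"
        if len(np.unique(psus[pooled])) < 2:
            others = np.unique(merged[~pooled])
            if len(others) == 0:
                raise ValidationError("cannot collapse: no second PSU available")
            # a lone single-PSU stratum: fold it into the first other stratum
            merged = np.where(pooled, others[0], merged)
        return SurveyDesign(strata=merged, psus=psus, weights=self.weights)


@dataclass(frozen=True)
class SurveyEstimate:
    """A survey mean with its SE, symmetric CI and design df."""

    mean: float
    se: float
    lcl: float
    ucl: float
    df: int
    level: float = 0.99

    @property
    def lcl99(self) -> float:
        return self.lcl

    @property
    def ucl99(self) -> float:
        return self.ucl


def weighted_mean(values, weights) -> float:
    """Σ w·y / Σ w."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape:
        raise ValidationError("values and weights must have equal length")
    if values.size == 0:
        raise ValidationError("weighted_mean: empty input")
    if not np.all(weights > 0):
        raise ValidationError("weights must be > 0")
    return float(np.sum(weights * values) / np.sum(weights))


def survey_estimate(
    values,
    design: SurveyDesign,
    level: float = 0.99,
    collapse_single_psu: bool = False,
) -> SurveyEstimate:
    """Weighted mean, linearized SE and t-based CI under the design."""
    values = np.asarray(values, dtype=float)
    design = SurveyDesign.from_arrays(design.strata, design.psus, design.weights)
    if values.shape != design.weights.shape:
        raise ValidationError("values and design must have equal length")
    design = design.validate_for_variance(collapse_single_psu)

    w = design.weights
    mean = weighted_mean(values, w)
    z = w * (values - mean)

    strata = design.strata.astype(str)
    psus = design.psus.astype(str)
    var_total = 0.0
    n_psu_total = 0
    strata_labels = np.unique(strata)
    for h in strata_labels:
        in_h = strata == h
        psu_labels = np.unique(psus[in_h])
        n_h = len(psu_labels)
        n_psu_total += n_h
        z_psu = np.array([z[in_h & (psus == p)].sum() for p in psu_labels])
        zbar = z_psu.mean()
        var_total += n_h / (n_h - 1) * np.sum((z_psu - zbar) ** 2)
    var = var_total / np.sum(w) ** 2

    df = int(n_psu_total - len(strata_labels))
    se = float(np.sqrt(var))
    if df <= 0:
        raise ValidationError("non-positive design degrees of freedom")
    t = stats.t.ppf(1 - (1 - level) / 2, df)
    return SurveyEstimate(
        mean=mean, se=se, lcl=mean - t * se, ucl=mean + t * se, df=df, level=level
    )


def meaningful_difference(a: SurveyEstimate, b: SurveyEstimate) -> bool:
    """True iff the closed CIs are disjoint (touching endpoints overlap)."""
    if a.level != b.level:
        raise ValidationError("estimates at different confidence levels")
    return a.ucl < b.lcl or b.ucl < a.lcl
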